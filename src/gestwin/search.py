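"""Model fitting by meta-modeling plus exhaustive random search.

Free parameters of constant-effect classes are drawn independently per
candidate: effect size ``gamma ~ Unif(-5, 5)``, minor allele frequency
``p ~ Unif(0, 0.5)`` and locus count ``n ~ 1 + Poisson(1)``.  Each candidate
is scored by simulating a cohort and computing the weighted quantile cost
against the reference table.

The summary ``sum(gamma * p * n)`` over the free classes is a strong
predictor of cost, which motivates a two-stage *meta-modeling* search: an
unconstrained stage maps cost against the sum statistic, a narrow interval
of the statistic around the best candidates is retained, and a second stage
samples only candidates whose statistic falls inside the interval (by
rejection, preserving the marginal draw distributions).  Finally the top 20
candidates are re-scored with the iterative simulator — the slower but fully
general engine — and re-ranked, so that engine discretisation differences
cannot decide the ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genotypes import GAMMA_SEARCH_BOUND, LocusClass
from .models import ModelSpec
from .quantile_cost import ModelEvaluation, QuantileTable, evaluate_model

__all__ = [
    "Candidate",
    "SearchResult",
    "FitConfig",
    "sum_gamma_p_n",
    "draw_candidate",
    "random_search",
    "metamodel_restrict",
    "fit_model",
]


def sum_gamma_p_n(classes: Sequence[LocusClass]) -> float:
    """``sum(gamma * maf * count)`` over the given locus classes."""
    return float(sum(lc.gamma * lc.maf * lc.count for lc in classes))


def _constrained_sum(spec: ModelSpec, classes: Sequence[LocusClass]) -> float:
    """Sum statistic over the classes carrying free parameters.

    Classes that are entirely pinned (e.g. the fixed varying-effect classes)
    shift the statistic by a constant and are excluded.
    """
    idx = spec.free_class_indices
    return sum_gamma_p_n([classes[k] for k in idx]) if idx else sum_gamma_p_n(classes)


def draw_candidate(
    spec: ModelSpec, rng: np.random.Generator
) -> tuple[LocusClass, ...]:
    """Draw one concrete parameter assignment for the spec's free parameters."""
    if spec.n_free_params == 0:
        raise ValueError(
            f"model {spec.name!r} has no free parameters; use evaluate_model directly"
        )
    out = []
    for lc, mask in zip(spec.classes, spec.free):
        kwargs = {}
        if "gamma" in mask:
            kwargs["gamma"] = rng.uniform(-GAMMA_SEARCH_BOUND, GAMMA_SEARCH_BOUND)
        if "maf" in mask:
            p = rng.uniform(0.0, 0.5)
            while p == 0.0:  # maf must be strictly positive
                p = rng.uniform(0.0, 0.5)
            kwargs["maf"] = p
        if "count" in mask:
            kwargs["count"] = int(1 + rng.poisson(1.0))
        out.append(replace(lc, **kwargs) if kwargs else lc)
    return tuple(out)


@dataclass(frozen=True)
class Candidate:
    """One scored parameter assignment."""

    classes: tuple[LocusClass, ...]
    evaluation: ModelEvaluation
    sum_gpn: float
    stage: str = "stage1"
    final_evaluation: ModelEvaluation | None = None

    @property
    def mean_cost(self) -> float:
        return self.evaluation.mean_cost

    @property
    def ranking_cost(self) -> float:
        ev = self.final_evaluation or self.evaluation
        return ev.mean_cost


@dataclass
class SearchResult:
    """Ranked candidates from a (possibly multi-stage) search."""

    spec: ModelSpec
    candidates: list[Candidate]
    top: list[Candidate] = field(default_factory=list)
    interval: tuple[float, float] | None = None
    seed_state: str = ""

    def __post_init__(self) -> None:
        self.candidates.sort(key=lambda c: c.mean_cost)

    @property
    def best(self) -> Candidate:
        return self.top[0] if self.top else self.candidates[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {
                "mean_cost": c.mean_cost,
                "sd_cost": c.evaluation.sd_cost,
                "sum_gpn": c.sum_gpn,
                "stage": c.stage,
                "final_cost": c.final_evaluation.mean_cost if c.final_evaluation else math.nan,
            }
            for k, lc in enumerate(c.classes):
                row[f"gamma{k + 1}"] = lc.gamma
                row[f"maf{k + 1}"] = lc.maf
                row[f"count{k + 1}"] = lc.count
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        best = self.best
        payload = {
            "model": self.spec.name,
            "n_candidates": len(self.candidates),
            "interval": list(self.interval) if self.interval else None,
            "best": {
                "mean_cost": best.ranking_cost,
                "sum_gpn": best.sum_gpn,
                "classes": [
                    {"kind": lc.kind, "gamma": lc.gamma, "maf": lc.maf, "count": lc.count}
                    for lc in best.classes
                ],
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _score(
    spec: ModelSpec,
    classes: tuple[LocusClass, ...],
    ref: QuantileTable,
    n_pairs: int,
    replicates: int,
    rng: np.random.Generator,
    engine: str,
    stage: str,
) -> Candidate:
    ev = evaluate_model(
        spec.with_classes(classes), ref, n_pairs, replicates, rng, engine=engine
    )
    return Candidate(classes, ev, _constrained_sum(spec, classes), stage)


def random_search(
    spec: ModelSpec,
    ref: QuantileTable,
    budget: int,
    n_pairs: int,
    replicates: int,
    rng: np.random.Generator,
    engine: str = "auto",
    sampler: Callable[[np.random.Generator], tuple[LocusClass, ...]] | None = None,
    stage: str = "stage1",
) -> SearchResult:
    """Draw ``budget`` candidates, score each, and return them ranked.

    ``sampler`` overrides the default free-parameter draw (used by the
    constrained second stage); results are deterministic given the RNG state.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    draw = sampler if sampler is not None else (lambda r: draw_candidate(spec, r))
    cands = [
        _score(spec, draw(rng), ref, n_pairs, replicates, rng, engine, stage)
        for _ in range(budget)
    ]
    return SearchResult(spec=spec, candidates=cands)


def metamodel_restrict(
    stage1: SearchResult,
    keep_fraction: float = 0.01,
    margin: float = 0.1,
    min_width: float = 0.01,
) -> tuple[float, float]:
    """Interval of the sum statistic spanned by the lowest-cost candidates.

    The best ``keep_fraction`` of candidates (at least one) define the raw
    interval, which is widened by ``margin`` times its length on each side;
    a degenerate interval is widened symmetrically to ``min_width``.
    """
    cands = stage1.candidates
    if len(cands) < 100:
        raise ValueError("meta-modeling needs at least 100 stage-1 candidates")
    n_keep = max(1, int(round(keep_fraction * len(cands))))
    vals = np.array([c.sum_gpn for c in cands[:n_keep]])
    lo, hi = float(vals.min()), float(vals.max())
    width = hi - lo
    if width < min_width:
        mid = 0.5 * (lo + hi)
        lo, hi = mid - min_width / 2, mid + min_width / 2
        width = min_width
    return lo - margin * width, hi + margin * width


@dataclass(frozen=True)
class FitConfig:
    """Budgets and sizes for a two-stage model fit."""

    stage1_budget: int = 10_000
    stage2_budget: int = 10_000
    n_pairs: int = 35_541
    replicates: int = 1
    keep_fraction: float = 0.01
    margin: float = 0.1
    top_k: int = 20
    final_replicates: int = 10
    engine: str = "auto"
    max_rejection_factor: int = 100_000


def fit_model(
    spec: ModelSpec,
    ref: QuantileTable,
    config: FitConfig,
    rng: np.random.Generator,
) -> SearchResult:
    """Full fit: unconstrained search, sum-statistic restriction, final re-score.

    Models without free parameters are evaluated once (no search); models
    flagged without meta-modeling skip the restriction stage.  The top
    ``top_k`` candidates are always re-scored with the iterative engine at
    ``final_replicates`` replicates and re-ranked among themselves.
    """
    if spec.n_free_params == 0:
        ev = evaluate_model(
            spec, ref, config.n_pairs, max(config.final_replicates, 1), rng,
            engine=config.engine,
        )
        cand = Candidate(spec.classes, ev, _constrained_sum(spec, spec.classes), "evaluate")
        return SearchResult(spec=spec, candidates=[cand], top=[cand])

    result = random_search(
        spec, ref, config.stage1_budget, config.n_pairs, config.replicates, rng,
        engine=config.engine, stage="stage1",
    )
    interval = None
    if spec.use_metamodel and config.stage2_budget > 0:
        interval = metamodel_restrict(result, config.keep_fraction, config.margin)
        lo, hi = interval

        def constrained(r: np.random.Generator) -> tuple[LocusClass, ...]:
            for _ in range(config.max_rejection_factor):
                classes = draw_candidate(spec, r)
                if lo <= _constrained_sum(spec, classes) <= hi:
                    return classes
            raise RuntimeError(
                f"rejection sampling could not hit the interval [{lo:.4g}, {hi:.4g}]"
            )

        stage2 = random_search(
            spec, ref, config.stage2_budget, config.n_pairs, config.replicates, rng,
            engine=config.engine, sampler=constrained, stage="stage2",
        )
        result = SearchResult(
            spec=spec, candidates=result.candidates + stage2.candidates
        )

    # final re-scoring of the best candidates with the iterative engine
    top = []
    for cand in result.candidates[: config.top_k]:
        ev = evaluate_model(
            spec.with_classes(cand.classes), ref, config.n_pairs,
            config.final_replicates, rng, engine="iterative",
        )
        top.append(replace(cand, final_evaluation=ev, stage=cand.stage + "+final"))
    top.sort(key=lambda c: c.ranking_cost)
    return SearchResult(spec=spec, candidates=result.candidates, top=top, interval=interval)
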