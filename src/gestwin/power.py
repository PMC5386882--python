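"""Empirical GWAS power and type-I-error analysis on simulated cohorts.

Each locus is tested marginally in two ways on a cohort of unrelated
individuals: a univariate linear regression of gestational age (days) on the
additive 0/1/2 genotype, and a Wald test of the genotype coefficient in a
single-covariate Cox proportional-hazards model.  Power is the fraction of
replicates whose p-value falls below the genome-wide threshold 5e-8;
calibration is assessed on null control loci (default MAFs 0.015 and 0.3).

Simulated gestational ages are integer days, so event times are heavily
tied; the partial likelihood uses the Efron tie approximation.  The Cox
solver here is a dedicated Newton maximiser for the one-covariate case,
vectorised over risk sets — power runs need tens of thousands of fits.
Day-300-capped outcomes enter as observed events by default (induction at
term is a delivery, not a loss to follow-up); censoring them instead is a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engines import simulate_individuals
from .genotypes import draw_independent_genotypes, locus_labels
from .models import ModelSpec

__all__ = [
    "GENOME_WIDE_THRESHOLD",
    "CoxFit",
    "linear_test",
    "cox_wald_test",
    "PowerResult",
    "power_analysis",
    "type1_table",
]

GENOME_WIDE_THRESHOLD = 5e-8


def linear_test(genotype: np.ndarray, phenotype: np.ndarray) -> float:
    """Two-sided slope p-value of a single-predictor least-squares fit.

    Returns ``nan`` for a constant genotype vector (the test is undefined;
    callers count such replicates separately).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.size < 3 or y.size != g.size:
        raise ValueError("need n >= 3 paired observations")
    if np.all(g == g[0]):
        return math.nan
    return float(stats.linregress(g, y).pvalue)


@dataclass(frozen=True)
class CoxFit:
    """One-covariate Cox fit: coefficient, its SE, and the Wald test."""

    beta: float
    se: float
    z: float
    pvalue: float
    loglik: float
    converged: bool
    n_iter: int


def _efron_quantities(
    beta: float, g: np.ndarray, w_event_sums: tuple, starts: np.ndarray,
    d: np.ndarray, event: np.ndarray, frac: np.ndarray, grp: np.ndarray,
) -> tuple[float, float, float]:
    """Log-likelihood, score and information of the Efron partial likelihood.

    Arrays are pre-sorted by time ascending; ``starts`` indexes the first
    member of each unique event time, ``d`` the death count per time,
    ``frac`` the Efron tie fractions ``l/d`` per death, ``grp`` the event
    time group of each death.
    """
    w = np.exp(beta * g)
    wg = w * g
    wg2 = wg * g
    # risk-set sums: everyone with time >= each unique event time
    S0 = np.cumsum(w[::-1])[::-1][starts]
    S1 = np.cumsum(wg[::-1])[::-1][starts]
    S2 = np.cumsum(wg2[::-1])[::-1][starts]
    # tie-set sums over deaths at each unique event time
    we = np.where(event, w, 0.0)
    s0 = np.add.reduceat(we, starts)
    s1 = np.add.reduceat(np.where(event, wg, 0.0), starts)
    s2 = np.add.reduceat(np.where(event, wg2, 0.0), starts)
    D0 = S0[grp] - frac * s0[grp]
    D1 = S1[grp] - frac * s1[grp]
    D2 = S2[grp] - frac * s2[grp]
    r = D1 / D0
    g_events = w_event_sums[0]
    loglik = beta * g_events - float(np.sum(np.log(D0)))
    score = g_events - float(np.sum(r))
    info = float(np.sum(D2 / D0 - r * r))
    return loglik, score, info


def _prepare_cox(g, time, event):
    g = np.asarray(g, dtype=float)
    time = np.asarray(time, dtype=float)
    if event is None:
        event = np.ones(g.size, dtype=bool)
    else:
        event = np.asarray(event, dtype=bool)
    if g.size < 3 or time.size != g.size or event.size != g.size:
        raise ValueError("need n >= 3 aligned observations")
    if not event.any():
        raise ValueError("need at least one event")
    order = np.argsort(time, kind="stable")
    g, time, event = g[order], time[order], event[order]
    # unique times that contain at least one event
    uniq, starts_all = np.unique(time, return_index=True)
    ends_all = np.append(starts_all[1:], time.size)
    d = np.array(
        [int(event[s:e].sum()) for s, e in zip(starts_all, ends_all)], dtype=np.int64
    )
    keep = d > 0
    starts, d = starts_all[keep], d[keep]
    grp = np.repeat(np.arange(d.size), d)
    l_within = np.arange(d.sum()) - np.repeat(np.cumsum(d) - d, d)
    frac = l_within / np.repeat(d, d)
    return g, time, event, starts, d, frac, grp


def cox_wald_test(
    genotype: np.ndarray,
    time: np.ndarray,
    event: np.ndarray | None = None,
    max_iter: int = 30,
    tol: float = 1e-10,
) -> CoxFit:
    """Wald test of a single covariate in a Cox model with Efron ties.

    Newton-Raphson from ``beta = 0`` with step halving; a monotone partial
    likelihood (``|beta|`` diverging) is flagged as non-converged.
    """
    g0 = np.asarray(genotype, dtype=float)
    if np.all(g0 == g0[0]):
        return CoxFit(math.nan, math.nan, math.nan, math.nan, math.nan, False, 0)
    g, time, event, starts, d, frac, grp = _prepare_cox(g0, time, event)
    g_event_sum = float(g[event].sum())
    beta = 0.0
    ll, score, info = _efron_quantities(beta, g, (g_event_sum,), starts, d, event, frac, grp)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0 or not math.isfinite(info):
            break
        step = score / info
        new_beta = beta + step
        new = _efron_quantities(new_beta, g, (g_event_sum,), starts, d, event, frac, grp)
        halvings = 0
        while (not math.isfinite(new[0]) or new[0] < ll - 1e-12) and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new = _efron_quantities(new_beta, g, (g_event_sum,), starts, d, event, frac, grp)
            halvings += 1
        beta, (ll, score, info) = new_beta, new
        if abs(score) < tol * max(1.0, abs(g_event_sum)) or abs(step) < 1e-12:
            converged = True
            break
    if abs(beta) > 15.0:  # monotone likelihood: estimate diverging
        converged = False
    se = 1.0 / math.sqrt(info) if info > 0 else math.nan
    z = beta / se if se and math.isfinite(se) else math.nan
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else math.nan
    return CoxFit(beta, se, z, float(p), ll, converged, it)


@dataclass
class PowerResult:
    """Detection and calibration rates per locus, sample size and test."""

    power: pd.DataFrame       # locus, n, test, power, reps, n_failed
    control: pd.DataFrame     # locus, n, test, level, rate
    threshold: float
    reps: int
    pvalues: dict = field(default_factory=dict)

    def write(self, power_path, control_path=None) -> None:
        self.power.to_csv(power_path, sep="\t", index=False)
        if control_path is not None:
            self.control.to_csv(control_path, sep="\t", index=False)


def _collect_pvalues(
    spec: ModelSpec,
    n: int,
    reps: int,
    control_mafs: Sequence[float],
    rng: np.random.Generator,
    censor_at_cap: bool,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """P-value arrays (reps x loci) for both tests on fresh cohorts."""
    causal = locus_labels(spec.classes)
    controls = [f"control_maf{p:g}" for p in control_mafs]
    labels = causal + controls
    cap = spec.resolved_baseline().cap_day
    p_lin = np.full((reps, len(labels)), np.nan)
    p_cox = np.full((reps, len(labels)), np.nan)
    for r in range(reps):
        gmat, ga = simulate_individuals(spec, n, rng)
        cols = [gmat[:, j] for j in range(gmat.shape[1])] if gmat is not None else []
        for p in control_mafs:
            cols.append(draw_independent_genotypes(p, n, rng))
        event = (ga < cap) if censor_at_cap else None
        for j, gcol in enumerate(cols):
            p_lin[r, j] = linear_test(gcol, ga)
            fit = cox_wald_test(gcol, ga, event)
            if fit.converged:
                p_cox[r, j] = fit.pvalue
    return causal, controls, p_lin, p_cox


def power_analysis(
    spec: ModelSpec,
    sample_sizes: Sequence[int] = (100, 500, 1000, 5000, 20000, 50000),
    reps: int = 1000,
    threshold: float = GENOME_WIDE_THRESHOLD,
    rng: np.random.Generator | None = None,
    control_mafs: Sequence[float] = (0.015, 0.3),
    nominal_levels: Sequence[float] = (0.05, GENOME_WIDE_THRESHOLD),
    censor_at_cap: bool = False,
    store_pvalues: bool = False,
) -> PowerResult:
    """Empirical detection rates of every locus across sample sizes.

    For each sample size, ``reps`` cohorts are simulated under ``spec``; two
    null control loci are appended to every cohort; every locus is tested by
    linear and Cox regression.  Power is the fraction of assessable
    replicates below ``threshold``; control loci are tabulated at the
    ``nominal_levels``.
    """
    if rng is None:
        raise ValueError("an explicit seeded Generator is required")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(n < 10 for n in sample_sizes):
        raise ValueError("sample sizes must be >= 10")
    power_rows, control_rows, pvals = [], [], {}
    for n in sample_sizes:
        causal, controls, p_lin, p_cox = _collect_pvalues(
            spec, n, reps, control_mafs, rng, censor_at_cap
        )
        labels = causal + controls
        if store_pvalues:
            pvals[n] = {"linear": p_lin, "cox": p_cox, "labels": labels}
        for test, mat in (("linear", p_lin), ("cox", p_cox)):
            for j, lab in enumerate(labels):
                col = mat[:, j]
                ok = np.isfinite(col)
                n_ok = int(ok.sum())
                if lab in set(causal):
                    power_rows.append(
                        {
                            "locus": lab,
                            "n": n,
                            "test": test,
                            "power": float((col[ok] < threshold).mean()) if n_ok else math.nan,
                            "reps": reps,
                            "n_failed": reps - n_ok,
                        }
                    )
                else:
                    for level in nominal_levels:
                        control_rows.append(
                            {
                                "locus": lab,
                                "n": n,
                                "test": test,
                                "level": level,
                                "rate": float((col[ok] < level).mean()) if n_ok else math.nan,
                                "reps": reps,
                                "n_failed": reps - n_ok,
                            }
                        )
    return PowerResult(
        power=pd.DataFrame(power_rows),
        control=pd.DataFrame(control_rows),
        threshold=threshold,
        reps=reps,
        pvalues=pvals,
    )


def type1_table(
    spec: ModelSpec,
    control_mafs: Sequence[float] = (0.015, 0.3),
    nominal_levels: Sequence[float] = (0.05, GENOME_WIDE_THRESHOLD),
    reps: int = 1000,
    n: int = 1000,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.99,
    censor_at_cap: bool = False,
) -> pd.DataFrame:
    """Null rejection rates of the control loci with binomial CIs.

    Cells where the expected minor-allele count ``2*n*maf`` is at most 3 are
    flagged: with one or two minor alleles in the sample, neither test is
    expected to hold its nominal level.
    """
    if rng is None:
        raise ValueError("an explicit seeded Generator is required")
    causal, controls, p_lin, p_cox = _collect_pvalues(
        spec, n, reps, control_mafs, rng, censor_at_cap
    )
    offset = len(causal)
    rows = []
    for test, mat in (("linear", p_lin), ("cox", p_cox)):
        for j, (lab, maf) in enumerate(zip(controls, control_mafs)):
            col = mat[:, offset + j]
            ok = np.isfinite(col)
            n_ok = int(ok.sum())
            for level in nominal_levels:
                k = int((col[ok] < level).sum())
                if n_ok:
                    ci = stats.binomtest(k, n_ok).proportion_ci(ci_level)
                    lo, hi = float(ci.low), float(ci.high)
                else:
                    lo = hi = math.nan
                rows.append(
                    {
                        "locus": lab,
                        "maf": maf,
                        "test": test,
                        "level": level,
                        "rate": k / n_ok if n_ok else math.nan,
                        "ci_low": lo,
                        "ci_high": hi,
                        "reps": reps,
                        "n_assessable": n_ok,
                        "low_count_flag": 2 * n * maf <= 3,
                    }
                )
    return pd.DataFrame(rows)
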