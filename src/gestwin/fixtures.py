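"""Synthetic stand-ins for register-derived inputs.

The clinical inputs of the original analysis — regression-adjusted
gestational ages of 35,541 maternal-cousin pairs, and the heights of the
corresponding sisters — come from a national birth register and are not
redistributable.  This module generates synthetic replacements with known
ground truth:

* :func:`make_reference_population` — a cousin-pair cohort simulated under a
  chosen model (default: the four fixed Gaussian-window classes of M3 plus a
  plausible constant-effect class), together with its conditional quantile
  table, which serves as the fitting reference.  It reproduces the
  qualitative nonuniform quantile pattern (lower quantiles climbing faster
  than upper ones); the true register quantile values are not reproduced.
* :func:`make_polygenic_control` — a height-like additive Gaussian trait
  driven by many small-effect loci shared between siblings, whose quantile
  pattern is uniform (parallel quantile series).  Note this is a plain
  additive trait, not a survival trait.

Every bundle carries a manifest (generating spec, baseline calibration,
seed, content hashes) sufficient to regenerate it byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .engines import PairCohort, simulate_pair_cohort
from .genotypes import CONSTANT, LocusClass, draw_sibling_genotype_pairs
from .models import ModelSpec, m3_varying_classes
from .quantile_cost import QuantileTable, conditional_quantile_table

__all__ = [
    "default_constant_class",
    "default_m3_like_spec",
    "make_reference_population",
    "make_polygenic_control",
    "TINY_N_PAIRS",
]

#: reduced cohort size for quick runs
TINY_N_PAIRS = 2000

#: |quantile_slope_contrast| below this counts as a uniform (parallel) pattern.
#: For the default height-like control the parallel quantile ascent is
#: ``(heritability / 2) * bin_width = 1.25`` trait units per bin; a contrast
#: under 40% of that is indistinguishable from parallel at register scale.
UNIFORMITY_CONTRAST_THRESHOLD = 0.5


def default_constant_class() -> LocusClass:
    """Default free constant-effect class of the reference fixture.

    Effect size 2.6 with two loci of MAF 0.01 — a plausible configuration in
    the region where constant-effect fits concentrate (effect sizes between
    2.4 and 2.8, rare alleles), chosen for the fixture rather than estimated.
    """
    return LocusClass(CONSTANT, gamma=2.6, maf=0.01, count=2)


def default_m3_like_spec() -> ModelSpec:
    """Generating model of the reference fixture: constant + 4 varying classes."""
    return ModelSpec(
        name="m3_like_fixture",
        classes=(default_constant_class(),) + m3_varying_classes(),
        free=(frozenset(),) * 5,
        engine="iterative",
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(spec: ModelSpec, n_pairs: int, seed: int, engine: str, extra: dict) -> dict:
    base = spec.resolved_baseline()
    return {
        "generator": f"gestwin {__version__}",
        "spec": spec.to_dict(),
        "baseline": {
            "rate": base.rate,
            "shape": base.shape,
            "origin_day": base.origin_day,
            "cap_day": base.cap_day,
            "calibration": "median GA 280 d, 10th percentile 266 d (continuous baseline-only model)",
        },
        "n_pairs": int(n_pairs),
        "seed": int(seed),
        "engine": engine,
        **extra,
    }


def make_reference_population(
    spec: ModelSpec | None = None,
    n_pairs: int = 35_541,
    seed: int = 0,
    bin_width: float = 7.0,
    min_count: int = 100,
    out_dir: str | Path | None = None,
) -> tuple[PairCohort, QuantileTable, dict]:
    """Simulate the reference cousin-pair population and its quantile table.

    The cohort is generated with the iterative engine (the generality check
    route); the retained-bin quantile table is the fitting target.  Ground
    truth parameters live in the returned manifest.
    """
    if spec is None:
        spec = default_m3_like_spec()
    rng = np.random.default_rng(seed)
    cohort = simulate_pair_cohort(spec, n_pairs, rng, engine="iterative")
    table = conditional_quantile_table(
        cohort, bin_width=bin_width, min_count=min_count, rng=rng
    )
    manifest = _manifest(
        spec, n_pairs, seed, "iterative",
        {"bin_width": bin_width, "min_count": min_count, "kind": "reference_population"},
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_path = out / "cohort.tsv"
        table_path = out / "quantile_table.tsv"
        cohort.write_tsv(cohort_path)
        table.write_tsv(table_path)
        manifest["files"] = {
            "cohort.tsv": _sha256(cohort_path),
            "quantile_table.tsv": _sha256(table_path),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    return cohort, table, manifest


def make_polygenic_control(
    n_pairs: int = 35_541,
    n_loci: int = 1000,
    heritability: float = 0.5,
    seed: int = 0,
    trait_mean: float = 165.0,
    trait_sd: float = 6.0,
    bin_width: float = 5.0,
    min_count: int = 100,
    out_dir: str | Path | None = None,
) -> tuple[PairCohort, QuantileTable, dict]:
    """Height-like polygenic sibling trait with a uniform quantile pattern.

    Each member's trait is a sum of small equal-variance additive
    contributions over ``n_loci`` shared sibling loci (MAFs drawn uniformly
    in [0.1, 0.5]) plus independent Gaussian noise; the additive fraction is
    ``heritability``, so the sibling trait correlation is ``heritability/2``.
    """
    if n_loci < 100:
        raise ValueError("polygenic control needs at least 100 loci")
    if not 0.0 <= heritability <= 1.0:
        raise ValueError("heritability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.1, 0.5, size=n_loci)
    # per-locus additive effect: equal variance share of the genetic variance
    var_g = heritability * trait_sd**2
    effects = np.sqrt(var_g / n_loci / (2 * mafs * (1 - mafs)))
    t1 = np.zeros(n_pairs)
    t2 = np.zeros(n_pairs)
    for p, a in zip(mafs, effects):
        g1, g2 = draw_sibling_genotype_pairs(p, n_pairs, rng)
        t1 += a * (g1 - 2 * p)
        t2 += a * (g2 - 2 * p)
    noise_sd = np.sqrt(max(trait_sd**2 - var_g, 0.0))
    t1 = trait_mean + t1 + rng.normal(0.0, noise_sd, n_pairs)
    t2 = trait_mean + t2 + rng.normal(0.0, noise_sd, n_pairs)
    cohort = PairCohort(t1, t2, meta={"kind": "polygenic_control", "seed": int(seed)})
    table = conditional_quantile_table(
        cohort, bin_width=bin_width, min_count=min_count, rng=rng,
        anchor=float(np.round(trait_mean)),
    )
    manifest = {
        "generator": f"gestwin {__version__}",
        "kind": "polygenic_control",
        "n_pairs": int(n_pairs),
        "n_loci": int(n_loci),
        "heritability": heritability,
        "trait_mean": trait_mean,
        "trait_sd": trait_sd,
        "bin_width": bin_width,
        "min_count": min_count,
        "seed": int(seed),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_path = out / "control_cohort.tsv"
        table_path = out / "control_quantile_table.tsv"
        cohort.write_tsv(cohort_path)
        table.write_tsv(table_path)
        manifest["files"] = {
            "control_cohort.tsv": _sha256(cohort_path),
            "control_quantile_table.tsv": _sha256(table_path),
        }
        with open(out / "control_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    return cohort, table, manifest
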