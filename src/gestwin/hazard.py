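"""Gompertz baseline hazard, genetic effect trajectories, and baseline fitting.

The phenotype is gestational age (GA) at spontaneous delivery, treated as a
time-to-event outcome.  Pregnancies enter the risk set at gestational day 150
(``t = 0``; earlier losses are considered unviable and out of scope), and all
simulated times are capped at day 300, mirroring post-term induction.

The baseline hazard is Gompertz, ``lambda0(t) = rate * exp(shape * t)``,
chosen among exponential / Weibull / Gompertz by AIC on register-like data.
Per-allele effects enter the log hazard either as a constant ``gamma``
(proportional hazards) or as a Gaussian window
``gamma / (sigma * sqrt(2*pi)) * exp(-((day - mu) / sigma)**2 / 2)``
parameterised in gestational days, so that the window integrates to ``gamma``.
The composite individual hazard is

    lambda(t) = rate * exp(shape * t) * exp(sum_i G_i * E_i(day)),

with ``G_i`` the additive genotype at locus ``i`` and ``day = 150 + t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .genotypes import CONSTANT, LocusClass

__all__ = [
    "BaselineHazard",
    "ParametricFit",
    "BaselineSelection",
    "baseline_hazard",
    "effect_trajectory",
    "total_hazard",
    "fit_parametric_baseline",
    "select_baseline",
    "FAMILIES",
]

FAMILIES = ("exponential", "weibull", "gompertz")

#: parameter count per family (used for AIC)
_N_PARAMS = {"exponential": 1, "weibull": 2, "gompertz": 2}


@dataclass(frozen=True)
class BaselineHazard:
    """Gompertz baseline: hazard ``rate * exp(shape * t)`` per day.

    ``t = 0`` corresponds to gestational day ``origin_day`` (150 by default);
    simulated GAs never exceed ``cap_day``.
    """

    rate: float
    shape: float
    origin_day: int = 150
    cap_day: int = 300

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.origin_day >= self.cap_day:
            raise ValueError("origin_day must precede cap_day")

    @property
    def horizon(self) -> int:
        """Days from the at-risk origin to the cap."""
        return self.cap_day - self.origin_day

    def hazard(self, t):
        return self.rate * np.exp(self.shape * np.asarray(t, dtype=float))

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.rate * _expm1_over_a(self.shape, t)

    def survival(self, t, multiplier: float = 1.0):
        """Closed-form S(t) for hazard ``multiplier * rate * exp(shape*t)``."""
        return np.exp(-multiplier * self.cumulative_hazard(t))


def _expm1_over_a(a: float, t):
    """Stable ``(exp(a*t) - 1) / a``, with the ``a -> 0`` limit ``t``."""
    t = np.asarray(t, dtype=float)
    if abs(a) < 1e-12:
        return t * (1.0 + a * t / 2.0)
    return np.expm1(a * t) / a


def baseline_hazard(t, base: BaselineHazard):
    """Baseline hazard at ``t`` days since the at-risk origin."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (days since the day-150 origin)")
    return base.hazard(t)


def effect_trajectory(lc: LocusClass, day):
    """Per-allele log-hazard contribution ``E(day)`` at gestational day ``day``.

    Constant classes return ``gamma`` for every day; varying classes return a
    Gaussian density window scaled to total mass ``gamma``, evaluated on the
    gestational-day scale (``mu = 230`` means day 230).
    """
    day = np.asarray(day, dtype=float)
    if lc.kind == CONSTANT:
        return np.broadcast_to(np.float64(lc.gamma), day.shape).copy() if day.shape else np.float64(lc.gamma)
    z = (day - lc.mu) / lc.sigma
    return lc.gamma / (lc.sigma * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * z * z)


def total_hazard(
    t,
    genotypes: np.ndarray,
    classes: Sequence[LocusClass],
    base: BaselineHazard,
):
    """Composite individual hazard at ``t`` days since origin.

    ``genotypes`` is the per-locus additive genotype vector, of length equal
    to the total expanded locus count ``sum(lc.count)``.
    """
    genotypes = np.asarray(genotypes)
    n_loci = sum(lc.count for lc in classes)
    if genotypes.shape != (n_loci,):
        raise ValueError(
            f"genotype vector length {genotypes.shape} does not match expanded locus count {n_loci}"
        )
    t = np.asarray(t, dtype=float)
    day = base.origin_day + t
    log_mult = np.zeros_like(day)
    pos = 0
    for lc in classes:
        dose = genotypes[pos : pos + lc.count].sum()
        pos += lc.count
        if dose:
            log_mult = log_mult + dose * effect_trajectory(lc, day)
    return baseline_hazard(t, base) * np.exp(log_mult)


@dataclass(frozen=True)
class ParametricFit:
    """Maximum-likelihood fit of one parametric survival family."""

    family: str
    params: dict = field(default_factory=dict)
    loglik: float = math.nan
    aic: float = math.nan
    n: int = 0
    converged: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
            "message": self.message,
        }


def _gompertz_profile_loglik(alpha: float, t: np.ndarray) -> tuple[float, float]:
    """Profile log-likelihood over ``alpha`` with ``lambda`` concentrated out.

    For fixed shape ``alpha`` the score in ``lambda`` has the closed-form root
    ``lambda_hat = n * alpha / sum(exp(alpha*t) - 1)`` (limit ``n / sum(t)``).
    """
    n = t.size
    denom = np.sum(_expm1_over_a(alpha, t))
    lam = n / denom
    ll = n * math.log(lam) + alpha * np.sum(t) - n
    return ll, lam


def fit_parametric_baseline(ga_days: np.ndarray, family: str) -> ParametricFit:
    """Fit one family by maximum likelihood on the shifted scale ``t = ga - 150``.

    All observations are treated as events (live births, no censoring).  A
    failed optimisation is returned as a non-converged fit with diagnostics
    rather than silently falling back.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    ga = np.asarray(ga_days, dtype=float)
    origin = 150.0
    if ga.size < 10:
        raise ValueError("need at least 10 observations to fit a baseline")
    if np.any(ga <= origin):
        raise ValueError("all gestational ages must exceed the day-150 origin")
    t = ga - origin
    n = t.size
    k = _N_PARAMS[family]

    if family == "exponential":
        lam = n / t.sum()
        ll = n * math.log(lam) - lam * t.sum()
        return ParametricFit(family, {"rate": lam}, ll, 2 * k - 2 * ll, n, True)

    if family == "weibull":
        try:
            c, _, scale = stats.weibull_min.fit(t, floc=0)
            ll = float(np.sum(stats.weibull_min.logpdf(t, c, loc=0, scale=scale)))
            ok = math.isfinite(ll)
            return ParametricFit(
                family, {"shape": c, "scale": scale}, ll, 2 * k - 2 * ll, n, ok,
                "" if ok else "non-finite log-likelihood",
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            return ParametricFit(family, {}, math.nan, math.nan, n, False, str(exc))

    # Gompertz: 1-D profile likelihood in the shape parameter
    res = optimize.minimize_scalar(
        lambda a: -_gompertz_profile_loglik(a, t)[0],
        bounds=(-0.5, 0.5),
        method="bounded",
        options={"xatol": 1e-10},
    )
    ll, lam = _gompertz_profile_loglik(res.x, t)
    ok = bool(res.success) and math.isfinite(ll)
    return ParametricFit(
        family,
        {"rate": lam, "shape": float(res.x)},
        ll,
        2 * k - 2 * ll,
        n,
        ok,
        "" if ok else str(res.message),
    )


def calibrate_baseline(
    median_day: float = 280.0,
    q10_day: float = 266.0,
    origin_day: int = 150,
    cap_day: int = 300,
) -> BaselineHazard:
    """Solve for Gompertz ``(rate, shape)`` hitting two survival landmarks.

    The continuous baseline-only model is pinned so that the median GA is
    ``median_day`` and the 10th percentile is ``q10_day`` (typical term
    distribution).  The shape follows from the ratio of cumulative hazards at
    the two landmarks; the rate then falls out in closed form.
    """
    tm = median_day - origin_day
    tq = q10_day - origin_day
    if not 0 < tq < tm:
        raise ValueError("landmarks must satisfy origin < q10 < median")
    target = math.log(0.5) / math.log(0.9)

    def ratio(a: float) -> float:
        return float(_expm1_over_a(a, tm) / _expm1_over_a(a, tq)) - target

    alpha = optimize.brentq(ratio, 1e-9, 1.0, xtol=1e-14)
    lam = math.log(2.0) / float(_expm1_over_a(alpha, tm))
    return BaselineHazard(rate=lam, shape=alpha, origin_day=origin_day, cap_day=cap_day)


_DEFAULT_BASELINE: BaselineHazard | None = None


def default_baseline() -> BaselineHazard:
    """The package-default calibrated baseline (computed once, cached)."""
    global _DEFAULT_BASELINE
    if _DEFAULT_BASELINE is None:
        _DEFAULT_BASELINE = calibrate_baseline()
    return _DEFAULT_BASELINE


@dataclass(frozen=True)
class BaselineSelection:
    best_family: str
    fits: dict


def select_baseline(ga_days: np.ndarray) -> BaselineSelection:
    """Fit all three families and select by minimum AIC.

    Ties (within 1e-9) are broken toward the family with fewer parameters;
    failed fits are kept in the report but excluded from selection.
    """
    fits = {fam: fit_parametric_baseline(ga_days, fam) for fam in FAMILIES}
    ok = {f: fit for f, fit in fits.items() if fit.converged}
    if not ok:
        raise RuntimeError("no baseline family converged")
    best = min(ok, key=lambda f: (round(ok[f].aic, 9), _N_PARAMS[f]))
    return BaselineSelection(best_family=best, fits=fits)
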