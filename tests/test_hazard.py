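"""Baseline hazard, effect trajectories, and parametric baseline fitting."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import gestwin as gw
from gestwin.engines import sample_survival_analytic
from gestwin.hazard import (
    BaselineHazard,
    baseline_hazard,
    calibrate_baseline,
    effect_trajectory,
    fit_parametric_baseline,
    select_baseline,
    total_hazard,
)


class TestBaselineHazard:
    def test_value_at_origin_and_exponential_limit(self):
        base = BaselineHazard(rate=0.01, shape=0.0)
        t = np.arange(0, 150.0)
        assert baseline_hazard(0.0, base) == pytest.approx(0.01)
        assert np.allclose(baseline_hazard(t, base), 0.01)

    def test_gompertz_formula(self):
        base = BaselineHazard(rate=1e-6, shape=0.05)
        assert baseline_hazard(100.0, base) == pytest.approx(1e-6 * math.exp(5.0), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            baseline_hazard(-1.0, BaselineHazard(rate=0.01, shape=0.1))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BaselineHazard(rate=0.0, shape=0.1)
        with pytest.raises(ValueError):
            BaselineHazard(rate=0.01, shape=0.1, origin_day=300, cap_day=300)

    def test_closed_form_survival_matches_integrated_hazard(self):
        base = BaselineHazard(rate=1e-4, shape=0.08)
        for t in [10.0, 60.0, 140.0]:
            num, _ = integrate.quad(lambda s: base.hazard(s), 0.0, t, epsabs=1e-12)
            assert float(base.survival(t)) == pytest.approx(math.exp(-num), abs=1e-8)


class TestEffectTrajectory:
    def test_constant_class(self):
        lc = gw.LocusClass("constant", gamma=2.6, maf=0.01)
        assert float(effect_trajectory(lc, 170.0)) == 2.6
        assert np.allclose(effect_trajectory(lc, np.arange(150.0, 300.0)), 2.6)

    def test_gaussian_peak_value(self):
        lc = gw.LocusClass("varying", gamma=100.0, maf=0.01, mu=230.0, sigma=10.0)
        peak = 100.0 / (10.0 * math.sqrt(2 * math.pi))
        assert float(effect_trajectory(lc, 230.0)) == pytest.approx(peak, rel=1e-12)
        assert peak == pytest.approx(3.98942, abs=1e-5)

    def test_gaussian_symmetry(self):
        lc = gw.LocusClass("varying", gamma=-100.0, maf=0.3, mu=258.0, sigma=10.0)
        d = np.linspace(0.0, 40.0, 17)
        assert np.allclose(
            effect_trajectory(lc, 258.0 - d), effect_trajectory(lc, 258.0 + d)
        )

    def test_gaussian_window_integrates_to_gamma(self):
        lc = gw.LocusClass("varying", gamma=60.0, maf=0.015, mu=244.0, sigma=10.0)
        val, _ = integrate.quad(
            lambda d: float(effect_trajectory(lc, d)), 244.0 - 120.0, 244.0 + 120.0
        )
        assert val == pytest.approx(60.0, abs=1e-6)


class TestTotalHazard:
    def test_no_loci_and_null_genotypes_reduce_to_baseline(self, base):
        t = np.linspace(0.0, 150.0, 7)
        assert np.allclose(total_hazard(t, np.array([]), [], base), baseline_hazard(t, base))
        classes = [gw.LocusClass("varying", gamma=80.0, maf=0.01, mu=237.0, sigma=10.0)]
        assert np.allclose(
            total_hazard(t, np.zeros(1), classes, base), baseline_hazard(t, base)
        )

    def test_constant_locus_multiplies_baseline(self, base):
        classes = [gw.LocusClass("constant", gamma=1.5, maf=0.1)]
        t = np.linspace(0.0, 100.0, 5)
        got = total_hazard(t, np.array([2]), classes, base)
        assert np.allclose(got, baseline_hazard(t, base) * math.exp(3.0))

    def test_all_constant_classes_are_proportional(self, base):
        classes = [
            gw.LocusClass("constant", gamma=1.5, maf=0.1, count=2),
            gw.LocusClass("constant", gamma=-0.5, maf=0.3),
        ]
        geno = np.array([1, 2, 1])
        t = np.linspace(0.0, 150.0, 31)
        ratio = total_hazard(t, geno, classes, base) / baseline_hazard(t, base)
        assert np.allclose(ratio, ratio[0])

    def test_genotype_length_mismatch(self, base):
        classes = [gw.LocusClass("constant", gamma=1.0, maf=0.1, count=3)]
        with pytest.raises(ValueError):
            total_hazard(10.0, np.array([1, 2]), classes, base)


class TestParametricFitting:
    def test_gompertz_recovery_at_large_n(self):
        true = BaselineHazard(rate=1e-3, shape=0.05)
        rng = np.random.default_rng(100)
        ga = sample_survival_analytic(true, 1.0, rng, size=100_000, discretize=False)
        fit = fit_parametric_baseline(ga, "gompertz")
        assert fit.converged
        assert fit.params["rate"] == pytest.approx(1e-3, rel=0.05)
        assert fit.params["shape"] == pytest.approx(0.05, rel=0.05)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    def test_shape_recovery_at_calibrated_baseline(self, base):
        rng = np.random.default_rng(101)
        ga = sample_survival_analytic(base, 1.0, rng, size=100_000, discretize=False)
        fit = fit_parametric_baseline(ga, "gompertz")
        assert fit.params["shape"] == pytest.approx(base.shape, rel=0.05)

    def test_gompertz_shape_near_zero_for_exponential_data(self):
        rng = np.random.default_rng(102)
        ga = 150.0 + rng.exponential(50.0, size=50_000)
        fit = fit_parametric_baseline(ga, "gompertz")
        # profile-likelihood curvature gives the SE of the shape estimate
        from gestwin.hazard import _gompertz_profile_loglik

        t = ga - 150.0
        h = 1e-5
        a = fit.params["shape"]
        d2 = (
            _gompertz_profile_loglik(a + h, t)[0]
            - 2 * _gompertz_profile_loglik(a, t)[0]
            + _gompertz_profile_loglik(a - h, t)[0]
        ) / h**2
        se = 1.0 / math.sqrt(-d2)
        assert abs(a) < 3 * se

    def test_matches_scipy_gompertz_mle(self):
        true = BaselineHazard(rate=2e-3, shape=0.04)
        rng = np.random.default_rng(103)
        ga = sample_survival_analytic(true, 1.0, rng, size=20_000, discretize=False)
        fit = fit_parametric_baseline(ga, "gompertz")
        # scipy parameterisation: hazard (c/s) * exp(t/s) -> rate = c/s, shape = 1/s
        c, _, s = stats.gompertz.fit(ga - 150.0, floc=0)
        assert fit.params["shape"] == pytest.approx(1.0 / s, rel=2e-2)
        assert fit.params["rate"] == pytest.approx(c / s, rel=5e-2)

    def test_loglik_invariant_under_permutation(self):
        rng = np.random.default_rng(104)
        ga = 150.0 + rng.weibull(3.0, 5_000) * 100.0
        fit1 = fit_parametric_baseline(ga, "weibull")
        fit2 = fit_parametric_baseline(rng.permutation(ga), "weibull")
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_parametric_baseline(np.full(5, 250.0), "gompertz")  # too few
        with pytest.raises(ValueError):
            fit_parametric_baseline(np.full(100, 120.0), "gompertz")  # below origin
        with pytest.raises(ValueError):
            fit_parametric_baseline(np.full(100, 250.0), "lognormal")


class TestSelection:
    def test_selects_generating_family(self, base):
        rng = np.random.default_rng(105)
        ga = sample_survival_analytic(base, 1.0, rng, size=100_000, discretize=False)
        sel = select_baseline(ga)
        assert sel.best_family == "gompertz"
        assert set(sel.fits) == {"exponential", "weibull", "gompertz"}

    def test_exponential_data_selects_exponential(self):
        rng = np.random.default_rng(106)
        ga = 150.0 + rng.exponential(40.0, size=100_000)
        assert select_baseline(ga).best_family == "exponential"


def test_calibrated_baseline_hits_landmarks():
    base = calibrate_baseline(median_day=280.0, q10_day=266.0)
    assert float(base.survival(130.0)) == pytest.approx(0.5, abs=1e-10)
    assert float(base.survival(116.0)) == pytest.approx(0.9, abs=1e-10)
    assert base.origin_day == 150 and base.cap_day == 300
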