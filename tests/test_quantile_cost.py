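"""Conditional quantile tables and the weighted sum-of-squares cost."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gestwin as gw
from gestwin.quantile_cost import (
    QUANTILE_LEVELS,
    QuantileTable,
    conditional_quantile_table,
    evaluate_model,
    quantile_slope_contrast,
    weighted_ss_cost,
)


def _table(bins, counts, quantiles, width=7.0):
    return QuantileTable(np.asarray(bins), np.asarray(counts), np.asarray(quantiles), width)


def reference_percentile(values, q):
    """Sort-and-interpolate percentile oracle (linear interpolation)."""
    x = np.sort(np.asarray(values, dtype=float))
    h = (x.size - 1) * q / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, x.size - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])


class TestConditionalQuantileTable:
    def test_degenerate_single_bin(self):
        ga = np.full(500, 280.0)
        qt = conditional_quantile_table((ga, ga))
        assert qt.n_bins == 1
        assert qt.bin_left[0] == 280.0 and qt.count[0] == 500
        assert np.all(qt.quantiles == 280.0)

    def test_retention_is_strictly_greater_than_100(self):
        # 100 pairs in one bin (dropped), 101 in another (kept)
        x1 = np.concatenate([np.full(100, 280.0), np.full(101, 287.0)])
        x2 = np.arange(201, dtype=float) + 200.0
        qt = conditional_quantile_table((x1, x2))
        assert qt.n_bins == 1
        assert qt.bin_left[0] == 287.0 and qt.count[0] == 101

    def test_empty_table_flag(self):
        qt = conditional_quantile_table((np.full(50, 280.0), np.full(50, 280.0)))
        assert qt.is_empty

    def test_bin_edges_are_anchored_multiples_of_seven(self):
        rng = np.random.default_rng(0)
        ga1 = rng.integers(200, 300, 30_000).astype(float)
        ga2 = rng.integers(200, 300, 30_000).astype(float)
        qt = conditional_quantile_table((ga1, ga2))
        assert np.all((qt.bin_left - 280.0) % 7.0 == 0.0)

    def test_percentiles_match_independent_oracle(self):
        rng = np.random.default_rng(1)
        ga1 = np.repeat([280.0, 287.0], 150)
        ga2 = rng.normal(280.0, 8.0, 300)
        qt = conditional_quantile_table((ga1, ga2), min_count=100)
        for i, left in enumerate(qt.bin_left):
            members = ga2[(ga1 >= left) & (ga1 < left + 7.0)]
            for j, lvl in enumerate(QUANTILE_LEVELS):
                assert qt.quantiles[i, j] == pytest.approx(
                    reference_percentile(members, lvl), abs=1e-10
                )

    def test_quantiles_are_monotone_within_bins(self):
        cohort = gw.simulate_pair_cohort(
            gw.default_m3_like_spec(), 10_000, np.random.default_rng(2)
        )
        qt = conditional_quantile_table(cohort, rng=np.random.default_rng(3))
        assert np.all(np.diff(qt.quantiles, axis=1) >= 0)

    def test_member_labels_exchangeable_in_expectation(self):
        # with random member relabelling, conditioning on ga1 vs ga2 is equivalent
        cohort = gw.simulate_pair_cohort(
            gw.default_m3_like_spec(), 20_000, np.random.default_rng(4)
        )
        qa = conditional_quantile_table(cohort, rng=np.random.default_rng(5))
        qb = conditional_quantile_table(
            (cohort.ga2, cohort.ga1), rng=np.random.default_rng(6)
        )
        shared = np.intersect1d(qa.bin_left, qb.bin_left)
        ia = np.isin(qa.bin_left, shared)
        ib = np.isin(qb.bin_left, shared)
        assert np.median(np.abs(qa.quantiles[ia] - qb.quantiles[ib])) < 2.0

    def test_tsv_roundtrip(self, tmp_path):
        qt = _table([273.0, 280.0], [200, 300], [[260, 270, 275, 280, 290]] * 2)
        path = tmp_path / "qt.tsv"
        qt.write_tsv(path)
        back = QuantileTable.read_tsv(path)
        assert np.array_equal(back.bin_left, qt.bin_left)
        assert np.array_equal(back.quantiles, qt.quantiles)


class TestWeightedCost:
    def test_identical_tables_cost_zero(self):
        qt = _table([280.0], [400], [[260, 270, 275, 280, 290]])
        assert weighted_ss_cost(qt, qt) == 0.0

    def test_hand_worked_single_bin_example(self):
        # one bin of 400 pairs, one quantile off by 2 d: sqrt(400) * 2^2 = 80
        ref = _table([280.0], [400], [[260, 270, 275, 280, 290]])
        sim = _table([280.0], [400], [[260, 270, 277, 280, 290]])
        assert weighted_ss_cost(sim, ref) == pytest.approx(80.0)

    def test_additive_over_bins(self):
        ref1 = _table([280.0], [400], [[260, 270, 275, 280, 290]])
        ref2 = _table([287.0], [100], [[262, 272, 277, 282, 292]])
        sim1 = _table([280.0], [999], [[261, 270, 275, 280, 290]])
        sim2 = _table([287.0], [999], [[262, 275, 277, 282, 292]])
        ref = _table([280.0, 287.0], [400, 100], np.vstack([ref1.quantiles, ref2.quantiles]))
        sim = _table([280.0, 287.0], [999, 999], np.vstack([sim1.quantiles, sim2.quantiles]))
        assert weighted_ss_cost(sim, ref) == pytest.approx(
            weighted_ss_cost(sim1, ref1) + weighted_ss_cost(sim2, ref2)
        )

    def test_weights_come_from_reference_counts(self):
        ref = _table([280.0], [400], [[260, 270, 275, 280, 290]])
        sim_small = _table([280.0], [10], [[260, 270, 277, 280, 290]])
        sim_big = _table([280.0], [4000], [[260, 270, 277, 280, 290]])
        assert weighted_ss_cost(sim_small, ref) == weighted_ss_cost(sim_big, ref)

    def test_missing_simulated_bin_penalty(self):
        ref = _table([280.0, 287.0], [400, 100], [[260, 270, 275, 280, 290]] * 2)
        sim = _table([280.0], [400], [[260, 270, 275, 280, 290]])
        expected = math.sqrt(100) * 5 * 25.0**2
        assert weighted_ss_cost(sim, ref) == pytest.approx(expected)

    def test_invariant_to_bin_order(self):
        ref = _table([280.0, 287.0], [400, 100], [[260, 270, 275, 280, 290],
                                                  [262, 272, 277, 282, 292]])
        sim = _table([287.0, 280.0], [1, 1], [[263, 272, 278, 282, 291],
                                              [261, 271, 275, 281, 290]])
        flipped = _table([280.0, 287.0], [1, 1], [[261, 271, 275, 281, 290],
                                                  [263, 272, 278, 282, 291]])
        assert weighted_ss_cost(sim, ref) == pytest.approx(weighted_ss_cost(flipped, ref))

    @given(st.floats(min_value=0.1, max_value=8.0))
    def test_scaling_deviations_scales_cost_quadratically(self, dev):
        ref = _table([280.0], [256], [[260, 270, 275, 280, 290]])
        sim1 = _table([280.0], [1], [[260 + dev, 270, 275, 280, 290 - dev]])
        sim2 = _table([280.0], [1], [[260 + 2 * dev, 270, 275, 280, 290 - 2 * dev]])
        c1 = weighted_ss_cost(sim1, ref)
        c2 = weighted_ss_cost(sim2, ref)
        assert c2 == pytest.approx(4 * c1, rel=1e-9)


class TestEvaluateModel:
    def test_single_replicate_has_undefined_sd(self, m1_reference, m1_truth_spec):
        ev = evaluate_model(
            m1_truth_spec, m1_reference, 5000, 1, np.random.default_rng(7)
        )
        assert math.isnan(ev.sd_cost) and ev.replicates == 1

    def test_generating_model_beats_m0(self, m1_reference, m1_truth_spec):
        rng = np.random.default_rng(8)
        ev_truth = evaluate_model(m1_truth_spec, m1_reference, 35_541, 3, rng)
        ev_m0 = evaluate_model(gw.model_m0(), m1_reference, 35_541, 3, rng)
        assert ev_m0.mean_cost > ev_truth.mean_cost

    def test_mean_cost_stable_across_root_seeds(self, m1_reference, m1_truth_spec):
        ev1 = evaluate_model(m1_truth_spec, m1_reference, 35_541, 5, np.random.default_rng(9))
        ev2 = evaluate_model(m1_truth_spec, m1_reference, 35_541, 5, np.random.default_rng(10))
        combined_sd = math.hypot(ev1.sd_cost, ev2.sd_cost) / math.sqrt(5)
        assert abs(ev1.mean_cost - ev2.mean_cost) < 3 * combined_sd


class TestSlopeContrast:
    def test_parallel_series_give_zero(self):
        q = np.arange(5.0)[None, :] + np.arange(6.0)[:, None] * 1.5
        qt = _table(280.0 + 7 * np.arange(6.0), [200] * 6, q)
        assert quantile_slope_contrast(qt) == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_bins(self):
        qt = _table([280.0, 287.0], [200, 200], [[260, 270, 275, 280, 290]] * 2)
        with pytest.raises(ValueError):
            quantile_slope_contrast(qt)

    def test_compressing_lower_quantiles_positive(self):
        # lower quantile climbing faster than upper -> positive contrast
        bins = 280.0 + 7 * np.arange(5.0)
        q05 = np.array([250.0, 255, 260, 265, 270])
        q95 = np.array([290.0, 290.5, 291, 291.5, 292])
        q = np.column_stack([q05, q05 + 10, q05 + 20, q95 - 5, q95])
        qt = _table(bins, [200] * 5, q)
        assert quantile_slope_contrast(qt) > 0
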