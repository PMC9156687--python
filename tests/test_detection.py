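"""Poisson detection test, scores, burst index, resampling machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from spikedeconv import (
    Correlogram,
    bootstrap_f1_compare,
    bootstrap_slope_compare,
    burst_index,
    compute_ach,
    confusion_and_f1,
    detect_connection,
    filter_pairs,
    normalized_slope,
    permutation_corr_test,
)
from spikedeconv.predictors import PredictorCurve
from conftest import poisson_train


def pred_flat(value, n=61):
    return PredictorCurve(np.full(n, float(value)), method="tails")


def cch_of(counts):
    return Correlogram(np.asarray(counts), 0.001, 1000, 1000)


class TestDetectConnection:
    def test_perfect_baseline_is_unlabelled(self):
        res = detect_connection(cch_of(np.full(61, 10)), pred_flat(10))
        assert res.label == "none"
        assert 0.3 < res.p_exc < 1.0 and 0.3 < res.p_inh < 1.0

    def test_excess_bin_detected_by_brute_force_tail(self):
        counts = np.full(61, 10)
        counts[30 + 3] = 30
        res = detect_connection(cch_of(counts), pred_flat(10), alpha=0.001)
        # upper tail P(X >= 30), summed directly from the pmf
        brute = sum(poisson.pmf(k, 10) for k in range(30, 200))
        assert res.p_exc == pytest.approx(brute, rel=1e-9)
        assert res.label == "excitatory"

    def test_mid_p_variant_matches_brute_force(self):
        counts = np.full(61, 10)
        counts[30 + 3] = 30
        res = detect_connection(cch_of(counts), pred_flat(10), mid_p=True)
        brute = sum(poisson.pmf(k, 10) for k in range(31, 200)) + 0.5 * poisson.pmf(30, 10)
        assert res.p_exc == pytest.approx(brute, rel=1e-9)

    def test_deficit_bin_detected_as_inhibitory(self):
        counts = np.full(61, 100)
        counts[30 + 2] = 40
        res = detect_connection(cch_of(counts), pred_flat(100), alpha=0.001)
        assert res.label == "inhibitory"

    def test_roisum_statistic(self):
        counts = np.full(61, 10)
        counts[30 + 1 : 30 + 6] += 8
        res = detect_connection(cch_of(counts), pred_flat(10), stat="roisum")
        assert res.p_exc == pytest.approx(poisson.sf(89, 50), rel=1e-9)

    def test_nonpositive_prediction_over_roi_rejected(self):
        with pytest.raises(ValueError):
            detect_connection(cch_of(np.full(61, 10)), pred_flat(0.0))

    def test_false_positive_rate_calibrated_on_null_pairs(self, rng):
        # independent Poisson pairs: excitatory FP rate at alpha = 0.001
        # stays below 0.005 for the median predictor
        from spikedeconv.predictors import predictor_median
        from spikedeconv import compute_cch

        n_pairs, fp = 1000, 0
        for _ in range(n_pairs):
            s1 = poisson_train(2.0, 600.0, rng, "a")
            s2 = poisson_train(8.0, 600.0, rng, "b")
            cch = compute_cch(s1, s2)
            res = detect_connection(cch, predictor_median(cch), alpha=0.001)
            fp += res.label == "excitatory"
        assert fp / n_pairs <= 0.005


class TestConfusionAndF1:
    def test_perfect_detection(self):
        labels = ["excitatory"] * 4 + ["inhibitory"] * 4 + ["none"] * 2
        cs = confusion_and_f1(labels, labels)
        assert cs.f1 == 1.0 and cs.tp == 0.8

    def test_hand_computed_rates(self):
        truth = ["excitatory"] * 9 + ["none"]
        pred = ["excitatory"] * 8 + ["none", "excitatory"]
        cs = confusion_and_f1(pred, truth)
        assert cs.tp == pytest.approx(0.8)
        assert cs.fp_exc == pytest.approx(0.1)
        assert cs.fn_exc == pytest.approx(0.1)
        assert cs.f1 == pytest.approx(0.8 / 0.9)

    def test_f1_strictly_decreases_when_a_hit_flips(self, rng):
        truth = ["excitatory"] * 6 + ["inhibitory"] * 6 + ["none"] * 3
        pred = list(truth)
        base = confusion_and_f1(pred, truth).f1
        for flip in ("none", "inhibitory"):
            worse = list(pred)
            worse[0] = flip
            assert confusion_and_f1(worse, truth).f1 < base

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_f1([], [])


class TestBurstIndex:
    def make_ach(self, head_sum, tail_sum):
        # concentrate the head sum at lag 5 ms and the tail sum at 40 ms
        counts = np.zeros(101, dtype=int)
        m = 50
        counts[m + 5] = counts[m - 5] = head_sum
        counts[m + 40] = counts[m - 40] = tail_sum
        return Correlogram(counts, 0.001, 100, 100, kind="ACH")

    def test_equal_window_sums_give_zero(self):
        assert burst_index(self.make_ach(5, 5)).burst_index == 0.0

    def test_hand_value(self):
        # head 30, tail 10 -> (30 - 10)/(30 + 10) = 0.5
        bm = burst_index(self.make_ach(30, 10))
        assert bm.burst_index == pytest.approx(0.5)
        assert bm.head == 30 and bm.tail == 10

    def test_window_edges_follow_definitions(self):
        counts = np.zeros(101, dtype=int)
        m = 50
        counts[m + 2] = 99  # lag 2 ms: outside (2, 10]
        counts[m + 10] = 7  # lag 10 ms: inside
        counts[m + 35] = 99  # lag 35 ms: outside (35, 50]
        counts[m + 50] = 3  # lag 50 ms: inside
        bm = burst_index(Correlogram(counts, 0.001, 10, 10, kind="ACH"))
        assert (bm.head, bm.tail) == (7, 3)

    def test_short_ach_and_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            burst_index(Correlogram(np.ones(61), 0.001, 10, 10, kind="ACH"))
        with pytest.raises(ValueError):
            burst_index(Correlogram(np.zeros(121), 0.001, 10, 10, kind="ACH"))

    def test_poisson_train_sits_at_flat_ach_value(self, rng):
        # a flat ACH gives (8 - 15)/23 ~ -0.304 because the head window
        # (2, 10] holds 8 bins and the tail window (35, 50] holds 15
        s = poisson_train(10.0, 600.0, rng)
        bi = burst_index(compute_ach(s, half_width_bins=50)).burst_index
        assert bi == pytest.approx((8 - 15) / 23, abs=0.08)


def outcome_table(n_correct, n_wrong, truth="excitatory"):
    rows = [{"truth": truth, "label": truth}] * n_correct
    rows += [{"truth": truth, "label": "none"}] * n_wrong
    return pd.DataFrame(rows)


class TestBootstrapF1:
    def test_exchangeable_groups_give_half(self):
        g = outcome_table(40, 10)
        res = bootstrap_f1_compare(g, g.copy(), n_iter=800, rng_seed=0)
        assert 0.35 < res["p"] < 0.65

    def test_separated_groups_give_zero(self):
        res = bootstrap_f1_compare(
            outcome_table(30, 0), outcome_table(0, 30), n_iter=300, rng_seed=0
        )
        assert res["p"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_f1_compare(outcome_table(5, 0), outcome_table(0, 0).iloc[:0])


class TestBootstrapSlope:
    def test_identical_groups(self, rng):
        x = np.arange(20.0)
        y = 2 * x + rng.normal(0, 1, 20)
        res = bootstrap_slope_compare(x, y, x, y, n_resamples=100, rng_seed=1)
        assert 0.3 < res["p"] < 0.7
        assert res["slopes"][0].size == 100

    def test_constructed_slope_ordering(self, rng):
        x = np.arange(30.0)
        y1 = 2 * x + rng.normal(0, 1, 30)
        y2 = 0 * x + rng.normal(0, 1, 30)
        res = bootstrap_slope_compare(x, y1, x, y2, n_resamples=60, rng_seed=1)
        assert res["p"] < 0.01  # slope1 < slope2 almost never

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_slope_compare([1, 2], [1, 2], [1, 2, 3], [1, 2, 3])


class TestPermutationCorr:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = permutation_corr_test(x, x, n_perm=200, rng_seed=0)
        assert res["rho"] == pytest.approx(1.0)
        assert res["p"] < 0.05

    def test_hand_rank_set(self):
        res = permutation_corr_test([1, 2, 3, 4], [2, 1, 4, 3], n_perm=100, rng_seed=0)
        assert res["rho"] == pytest.approx(0.6)

    def test_independent_data_null(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        res = permutation_corr_test(x, y, n_perm=400, rng_seed=0)
        assert abs(res["rho"]) < 0.35
        assert res["p"] > 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            permutation_corr_test([1, 1, 1], [1, 2, 3])


class TestNormalizedSlope:
    def test_flat_estimates_give_zero_slope(self):
        br = np.repeat([0.0, 0.2, 0.4], 5)
        est = np.full(15, 3.3)
        assert normalized_slope(br, est) == pytest.approx(0.0, abs=1e-12)

    def test_affine_construction_gives_unit_slope(self):
        br = np.repeat([0.0, 0.1, 0.2, 0.3, 0.4], 4)
        est = 2.5 * (1 + br)
        assert normalized_slope(br, est) == pytest.approx(1.0)

    def test_zero_mean_at_zero_burst_rejected(self):
        with pytest.raises(ValueError):
            normalized_slope([0.1, 0.2], [1.0, 2.0])


def test_filter_pairs_applies_all_four_criteria():
    table = pd.DataFrame(
        {
            "burst_index_pre": [0.2, -0.1, 0.3, 0.1, 0.4],
            "detected_raw": [True, True, False, True, True],
            "detected_dc": [True, True, True, True, True],
            "estg_raw": [0.01, 0.01, 0.01, 0.05, 0.01],
            "estg_dc": [0.012, 0.012, 0.012, 0.01, 0.012],
            "cch_counts": [500, 500, 500, 500, 300],
        }
    )
    mask = filter_pairs(table)
    # pair 0 passes; 1 fails burst index; 2 fails detection; 3 fails the
    # gain-ratio bounds; 4 fails the count floor
    assert mask.tolist() == [True, False, False, False, False]
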