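"""Signal-detection metrics, depth errors and paired statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import binoseg as bs
from binoseg import evaluation as ev


# -- independent oracles ----------------------------------------------------


def inverse_normal_cdf(p, tol=1e-12):
    """Bisection on the standard normal CDF (independent of scipy.ppf)."""
    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stats.norm.cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def brute_force_confusion(pred, truth, class_count):
    """Exhaustive per-pixel counting with python loops."""
    out = {c: dict(true=0, correct=0, from_bg=0, from_other=0)
           for c in range(class_count)}
    for p, t in zip(pred.ravel(), truth.ravel()):
        out[t]["true"] += 1
        if p == t:
            out[p]["correct"] += 1
        elif t == 0:
            out[p]["from_bg"] += 1
        else:
            out[p]["from_other"] += 1
    return out


# -- depth ------------------------------------------------------------------


class TestDepthErrorStats:
    def test_perfect_prediction(self):
        d = ev.depth_error_stats(np.full((4, 4), 0.3), np.full((4, 4), 0.3))
        assert d.mean_signed == 0 and d.sd_signed == 0 and d.rmse == 0

    def test_closed_form_example(self):
        d = ev.depth_error_stats(np.array([[0.1, 0.2]]), np.array([[0.0, 0.4]]))
        np.testing.assert_allclose(d.error_map, [[0.1, -0.2]])
        assert d.mean_signed == pytest.approx(-0.05)
        assert d.rmse == pytest.approx(np.sqrt(0.025))

    def test_constant_offset(self):
        truth = np.random.default_rng(0).random((8, 8))
        d = ev.depth_error_stats(truth + 0.1, truth)
        assert d.rmse == pytest.approx(0.1)
        assert d.sd_signed == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.depth_error_stats(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bias_variance_inequality(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((6, 6))
        truth = rng.random((6, 6))
        d = ev.depth_error_stats(pred, truth)
        assert d.mean_signed ** 2 <= d.rmse ** 2 + 1e-12
        assert abs(d.mean_signed) <= d.rmse + 1e-12


# -- confusion --------------------------------------------------------------


class TestSegmentationConfusion:
    def test_spec_worked_example(self):
        truth = np.array([[1, 1], [0, 2]])
        pred = np.array([[1, 2], [0, 2]])
        conf = ev.segmentation_confusion(pred, truth, class_count=3)
        rates = ev.detection_rates(conf)
        assert rates.loc[1, "hit_rate"] == pytest.approx(1 / 2)
        assert rates.loc[1, "fa_rate"] == pytest.approx(0 / 1)
        assert rates.loc[2, "hit_rate"] == pytest.approx(1 / 1)
        assert rates.loc[2, "fa_rate"] == pytest.approx(1 / 2)
        assert conf.attrs["pixel_accuracy"] == pytest.approx(3 / 4)

    def test_perfect_prediction(self):
        truth = np.random.default_rng(1).integers(0, 4, (10, 10))
        conf = ev.segmentation_confusion(truth, truth, 4)
        rates = ev.detection_rates(conf)
        present = rates["present"]
        assert (rates.loc[present, "hit_rate"] == 1).all()
        assert (rates.loc[present, "fa_rate"] == 0).all()
        assert conf.attrs["pixel_accuracy"] == 1.0

    def test_all_background_truth_flags_objects_absent(self):
        truth = np.zeros((5, 5), dtype=int)
        pred = np.random.default_rng(2).integers(0, 3, (5, 5))
        rates = ev.detection_rates(ev.segmentation_confusion(pred, truth, 3))
        assert not rates.loc[1:, "present"].any()
        assert rates.loc[1:, "hit_rate"].isna().all()

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            ev.segmentation_confusion(np.array([[5]]), np.array([[0]]), 3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_exhaustive_counting_and_conserves_pixels(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        truth = rng.integers(0, k, (16, 16))
        pred = rng.integers(0, k, (16, 16))
        conf = ev.segmentation_confusion(pred, truth, k)
        brute = brute_force_confusion(pred, truth, k)
        for c in range(k):
            assert conf.loc[c, "true_pixels"] == brute[c]["true"]
            assert conf.loc[c, "correct"] == brute[c]["correct"]
            assert conf.loc[c, "pred_from_background"] == (
                brute[c]["from_bg"] if c != 0 else conf.loc[0, "pred_from_background"])
            if c >= 1:
                assert conf.loc[c, "pred_from_other_objects"] == brute[c]["from_other"]
        assert conf["true_pixels"].sum() == truth.size
        assert conf["pred_total"].sum() == truth.size


# -- d-prime ----------------------------------------------------------------


class TestDPrime:
    def test_chance_performance_is_zero(self):
        assert ev.dprime_from_rates(0.5, 0.5, 100, 100) == pytest.approx(0.0)

    def test_matches_bisection_oracle_on_example(self):
        got = ev.dprime_from_rates(0.79, 0.003, 10**6, 10**6)
        expected = inverse_normal_cdf(0.79) - inverse_normal_cdf(0.003)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(0.806 - (-2.748), abs=2e-3)

    def test_agreement_with_oracle_on_grid(self):
        grid = [0.02, 0.1, 0.25, 0.5, 0.75, 0.9, 0.98]
        for h in grid:
            for f in grid:
                got = ev.dprime_from_rates(h, f, 10**9, 10**9)
                want = inverse_normal_cdf(h) - inverse_normal_cdf(f)
                assert got == pytest.approx(want, abs=1e-6)

    def test_strictly_increasing_in_hit_rate(self):
        ds = [ev.dprime_from_rates(h, 0.2, 50, 50)
              for h in (0.3, 0.5, 0.7, 0.9)]
        assert all(a < b for a, b in zip(ds, ds[1:]))

    def test_perfect_scores_clamped_finite(self):
        d = ev.dprime_from_rates(1.0, 0.0, 200, 400)
        assert np.isfinite(d)
        assert d == pytest.approx(stats.norm.ppf(1 - 1 / 400)
                                  - stats.norm.ppf(1 / 800))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.dprime_from_rates(1.2, 0.1, 10, 10)
        with pytest.raises(ValueError):
            ev.dprime_from_rates(0.5, 0.1, 0, 10)


class TestPerObjectTable:
    def test_perfect_segmentation_gives_clamped_max(self):
        truth = np.tile(np.arange(5), (20, 4))  # all 5 classes present
        rates = [ev.detection_rates(ev.segmentation_confusion(truth, truth, 5))
                 for _ in range(3)]
        table = ev.per_object_dprime_table(rates)
        assert len(table) == 5
        assert (table["mean_dprime"] > 0).all()
        assert np.isfinite(table["mean_dprime"]).all()

    def test_simulated_rates_recovered(self):
        # known per-class hit rates, large N: mean d' approx z(h) - z(f)
        rng = np.random.default_rng(8)
        class_hits = [0.95, 0.8, 0.6]
        fa = 0.01
        tables = []
        n = 4000
        for _img in range(40):
            rows = []
            for h in class_hits:
                h_obs = rng.binomial(n, h) / n
                f_obs = rng.binomial(n, fa) / n
                rows.append((h_obs, f_obs, n, n, True))
            df = pd.DataFrame(rows, columns=["hit_rate", "fa_rate", "n_true",
                                             "n_fa_pool", "present"])
            tables.append(df)
        table = ev.per_object_dprime_table(tables)
        for i, h in enumerate(class_hits):
            want = stats.norm.ppf(h) - stats.norm.ppf(fa)
            assert table.loc[i, "mean_dprime"] == pytest.approx(want, abs=0.08)


# -- paired stats -----------------------------------------------------------


class TestPairedComparison:
    def test_identical_samples_are_degenerate_null(self):
        r = ev.paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.t, r.p, r.cohen_d) == (0.0, 1.0, 0.0)

    def test_closed_form_example(self):
        r = ev.paired_comparison([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert r.t == pytest.approx(2 * np.sqrt(3))
        assert r.df == 2
        assert r.cohen_d == pytest.approx(2.0)

    def test_bonferroni_adjustment(self):
        r = ev.paired_comparison([2.0, 3.0, 4.0], [1.0, 1.0, 1.0],
                                 family_size=3)
        assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p))
        big = ev.paired_comparison([1.0, 2.0, 1.5], [1.1, 1.9, 1.4],
                                   family_size=50)
        assert big.p_adjusted == 1.0

    def test_zero_variance_nonzero_mean_rejected(self):
        with pytest.raises(ValueError):
            ev.paired_comparison([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        r = ev.paired_comparison(a, b, family_size=2)
        diff = a - b
        mean = sum(diff) / n
        sd = np.sqrt(sum((d - mean) ** 2 for d in diff) / (n - 1))
        assert r.t == pytest.approx(mean / (sd / np.sqrt(n)))
        assert r.cohen_d == pytest.approx(mean / sd)
        assert r.df == n - 1
        # cross-check p against scipy's paired test
        t_sp, p_sp = stats.ttest_rel(a, b)
        assert r.t == pytest.approx(t_sp)
        assert r.p == pytest.approx(p_sp)
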