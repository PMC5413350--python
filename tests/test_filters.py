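"""FPKM, window curves and the two learned depth thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dualseq import filters, simulate
from dualseq.filters import (
    ThresholdDetection,
    apply_absence_filter,
    detect_absence_threshold,
    detect_lower_limit,
    fpkm,
    window_curve,
)


class TestFpkm:
    def test_unit_definition(self):
        out = fpkm(pd.DataFrame({"s": [10]}), [1000], [1_000_000])
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        out = fpkm(pd.DataFrame({"s": [0, 5]}), [500, 500], [10_000])
        assert out.iloc[0, 0] == 0.0

    def test_zero_library_size_raises(self):
        with pytest.raises(ValueError, match="library"):
            fpkm(pd.DataFrame({"s": [0, 0]}), [500, 500])

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, size=(50, 4)))
        lengths = rng.integers(200, 5000, size=50)
        libs = rng.integers(10**5, 10**6, size=4)
        out = fpkm(counts, lengths, libs)
        for i in range(50):
            for j in range(4):
                expect = counts.iloc[i, j] / (lengths[i] / 1e3) / (libs[j] / 1e6)
                assert out.iloc[i, j] == pytest.approx(expect)


class TestWindowCurve:
    def test_constant_companion(self):
        ref = pd.Series(np.arange(200, dtype=float))
        comp = pd.Series(np.full(200, 7.0))
        curve = window_curve(ref, comp, window=50)
        assert np.all(curve.companion == 7.0)

    def test_window_count_arithmetic(self):
        ref = pd.Series(np.random.default_rng(1).random(150))
        curve = window_curve(ref, ref, window=100, step=1)
        assert len(curve) == 51

    def test_window_too_small_raises(self):
        ref = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            window_curve(ref, ref, window=1)

    def test_brute_force_median_oracle(self):
        rng = np.random.default_rng(2)
        ref = pd.Series(rng.lognormal(0, 1, 300), index=[f"g{i}" for i in range(300)])
        comp = pd.Series(rng.lognormal(0, 1, 300), index=ref.index)
        w = 40
        curve = window_curve(ref, comp, window=w)
        df = pd.DataFrame({"ref": ref, "comp": comp})
        df = df.sort_values(["ref"], kind="stable").sort_index(kind="stable")
        df = df.iloc[np.lexsort((df.index.astype(str), df["ref"].to_numpy()))]
        for k in range(0, 300 - w + 1, 37):
            block = df.iloc[k : k + w]
            assert curve.ref_median[k] == pytest.approx(float(np.median(block["ref"])))
            assert curve.companion[k] == pytest.approx(float(np.median(block["comp"])))


class TestLowerLimit:
    def test_globally_correlated_returns_first_window(self):
        rng = np.random.default_rng(3)
        ref = pd.Series(np.sort(rng.lognormal(0, 2, 1000)))
        comp = ref * rng.lognormal(0, 0.05, 1000)
        curve = window_curve(ref, comp, window=100, step=10)
        det = detect_lower_limit(curve, run_length=20)
        assert not det.failed
        assert det.value == pytest.approx(curve.ref_median[0])

    def test_pure_noise_flags_failure(self):
        rng = np.random.default_rng(4)
        ref = pd.Series(np.sort(rng.lognormal(0, 2, 1500)))
        comp = pd.Series(rng.lognormal(0, 1, 1500))
        curve = window_curve(ref, comp, window=100, step=10)
        det = detect_lower_limit(curve, run_length=20)
        assert det.failed and det.value == np.inf

    def test_run_length_exceeding_windows_raises(self):
        ref = pd.Series(np.arange(120, dtype=float))
        curve = window_curve(ref, ref, window=100)
        with pytest.raises(ValueError):
            detect_lower_limit(curve, run_length=50)

    def test_recovers_planted_floor_within_factor_two(self):
        """Median recovered threshold over seeds within [f0/2, 2 f0]."""
        f0 = 1.0
        vals = []
        for seed in range(15):
            ref, comp = simulate.simulate_correlation_onset(
                n_genes=2000, floor_fpkm=f0, seed=seed
            )
            curve = window_curve(ref, comp, window=100, step=10)
            vals.append(detect_lower_limit(curve, run_length=20).value)
        med = float(np.median(vals))
        assert 0.5 * f0 <= med <= 2.0 * f0

    def test_scale_equivariance(self):
        ref, comp = simulate.simulate_correlation_onset(n_genes=1500, seed=1)
        c = 37.0
        det1 = detect_lower_limit(window_curve(ref, comp, window=100, step=10))
        det2 = detect_lower_limit(window_curve(ref * c, comp * c, window=100, step=10))
        assert det2.value == pytest.approx(c * det1.value)

    def test_raising_noise_floor_raises_recovered_limit(self):
        lows, highs = [], []
        for seed in range(8):
            for f0, acc in ((0.5, lows), (8.0, highs)):
                ref, comp = simulate.simulate_correlation_onset(
                    n_genes=2000, floor_fpkm=f0, seed=seed
                )
                curve = window_curve(ref, comp, window=100, step=10)
                acc.append(detect_lower_limit(curve, run_length=20).value)
        assert np.median(highs) > np.median(lows)


class TestKendall:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sliding_tau_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        x = np.sort(rng.integers(0, 15, n).astype(float))  # ties likely
        y = rng.integers(0, 10, n).astype(float)
        ours = filters._sliding_kendall_tau(x, y, 20)
        for k in range(len(ours)):
            expect = stats.kendalltau(x[k : k + 20], y[k : k + 20]).statistic
            if np.isnan(expect):
                assert np.isnan(ours[k])
            else:
                assert ours[k] == pytest.approx(expect, abs=1e-12)


class TestAbsenceThreshold:
    def test_all_detected_returns_zero(self):
        ref = pd.Series(np.linspace(1, 100, 200))
        det = detect_absence_threshold(ref, pd.Series([True] * 200), window=20)
        assert det.value == 0.0

    def test_window_proportion_arithmetic(self):
        detected = pd.Series([True] * 97 + [False] * 3)
        ref = pd.Series(np.linspace(1, 2, 100))
        curve = filters.window_curve(ref, detected.astype(float), window=100, mode="proportion")
        assert curve.companion[0] == pytest.approx(0.97)
        assert curve.companion[0] >= 0.95

    def test_logistic_dropout_recovery_and_slope_removal(self):
        """Recovered threshold exceeds the logistic midpoint, and refitting
        the detection-vs-expression slope on the filtered genes shows no
        residual dependence."""
        import statsmodels.api as sm

        m = 10.0
        ref, detected = simulate.simulate_detection_dropout(
            n_genes=5000, midpoint_fpkm=m, slope=1.5, seed=3
        )
        det = detect_absence_threshold(ref, detected, window=100)
        assert det.value > m
        retained = apply_absence_filter(ref.index, ref, detected, det.value)
        keep = ref.index.isin(retained)

        def detection_slope(mask):
            x = sm.add_constant(np.log(ref[mask].to_numpy()))
            y = detected[mask].to_numpy().astype(float)
            return sm.OLS(y, x).fit().params[1]

        # pre-filter the detection probability climbs steeply with
        # expression; post-filter the dependence is within noise of zero
        assert detection_slope(np.ones(len(ref), bool)) > 0.1
        assert abs(detection_slope(keep)) < 0.02

    def test_monotone_in_detection_target(self):
        ref, detected = simulate.simulate_detection_dropout(n_genes=3000, seed=5)
        v90 = detect_absence_threshold(ref, detected, detection_target=0.90).value
        v99 = detect_absence_threshold(ref, detected, detection_target=0.99).value
        assert v99 >= v90

    def test_scale_equivariance(self):
        ref, detected = simulate.simulate_detection_dropout(n_genes=3000, seed=6)
        v = detect_absence_threshold(ref, detected).value
        v10 = detect_absence_threshold(ref * 10, detected).value
        assert v10 == pytest.approx(10 * v)


class TestApplyAbsenceFilter:
    def test_detected_always_retained(self):
        out = apply_absence_filter(["a"], pd.Series({"a": 0.001}), pd.Series({"a": True}), 5.0)
        assert out == {"a"}

    def test_boundary_exactly_at_threshold_retained(self):
        out = apply_absence_filter(["a"], pd.Series({"a": 5.0}), pd.Series({"a": False}), 5.0)
        assert out == {"a"}

    def test_enumeration_oracle(self):
        genes = [f"g{i}" for i in range(10)]
        ref = pd.Series(np.arange(10, dtype=float), index=genes)
        det = pd.Series([i % 2 == 0 for i in range(10)], index=genes)
        thr = 4.0
        out = apply_absence_filter(genes, ref, det, thr)
        expected = {g for g in genes if det[g] or ref[g] >= thr}
        assert out == expected

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(50)]
        ref = pd.Series(rng.lognormal(1, 1, 50), index=genes)
        det = pd.Series(rng.random(50) < 0.6, index=genes)
        once = apply_absence_filter(genes, ref, det, 3.0)
        twice = apply_absence_filter(sorted(once), ref, det, 3.0)
        assert once <= set(genes)
        assert twice == once
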