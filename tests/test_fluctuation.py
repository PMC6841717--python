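from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_rmsf
from migrastat import (
    ScalingFit,
    StepSeries,
    SyntheticSpec,
    detect_M,
    fit_alpha,
    gen_fgn,
    rmsf_analysis,
    rmsf_curve,
    scale_invariance,
)
from migrastat.exceptions import InsufficientDataError, ParameterError
from migrastat.scaling import default_scales


class TestRmsfCurve:
    def test_constant_series_has_zero_fluctuation(self):
        s = StepSeries(values=np.full(256, 3.7))
        curve = rmsf_curve(s)
        np.testing.assert_allclose(curve.statistic, 0.0, atol=1e-12)
        with pytest.raises(InsufficientDataError):
            fit_alpha(curve)

    def test_alternating_series_vanishes_at_even_window(self):
        u = np.tile([1.0, -1.0], 32)
        curve = rmsf_curve(StepSeries(values=u), scales=[1, 2, 4])
        f = dict(zip(curve.scales.astype(int), curve.statistic))
        assert f[2] == pytest.approx(0.0, abs=1e-12)
        assert f[4] == pytest.approx(0.0, abs=1e-12)
        assert f[1] > 0

    @pytest.mark.parametrize("delta_l0", [1, 5])
    def test_matches_bruteforce_enumeration(self, delta_l0):
        """Vectorized F(l) equals the direct enumeration of all offsets."""
        u = gen_fgn(SyntheticSpec(kind="fgn", H=0.7, n=300, seed=9)).values
        scales = [1, 2, 3, 5, 8, 13, 21, 34, 55]
        curve = rmsf_curve(StepSeries(values=u), scales=scales, delta_l0=delta_l0)
        expected = brute_rmsf(u, curve.scales.astype(int), delta_l0)
        np.testing.assert_allclose(curve.statistic, expected, rtol=1e-9, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-10, 10, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_shift_invariance(self, shift, seed):
        """Adding a constant to every step leaves F(l) unchanged (the mean
        cancels inside the variance)."""
        u = np.random.default_rng(seed).normal(size=128)
        base = rmsf_curve(StepSeries(values=u), scales=[1, 2, 4, 8, 16])
        shifted = rmsf_curve(StepSeries(values=u + shift), scales=[1, 2, 4, 8, 16])
        np.testing.assert_allclose(base.statistic, shifted.statistic, atol=1e-8)

    def test_too_large_scales_are_dropped(self):
        s = StepSeries(values=np.random.default_rng(0).normal(size=32))
        with pytest.warns(UserWarning, match="dropped"):
            curve = rmsf_curve(s, scales=[2, 4, 40])
        assert 40 not in curve.scales
        with pytest.raises(InsufficientDataError):
            rmsf_curve(s, scales=[40, 50])

    def test_invalid_stride(self):
        s = StepSeries(values=np.ones(64))
        with pytest.raises(ParameterError):
            rmsf_curve(s, delta_l0=0)


class TestFitAlpha:
    def test_exact_power_law_recovered(self):
        l = np.arange(1, 101)
        curve = ScalingFit(scales=l, statistic=l**0.7, method_tag="rmsf")
        fit = fit_alpha(curve)
        assert fit.exponent == pytest.approx(0.7, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_points_excluded_then_too_few(self):
        l = np.arange(1, 7)
        stat = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            fit_alpha(ScalingFit(scales=l, statistic=stat))


class TestDetectM:
    def _grid(self, n=4000):
        return default_scales(n)

    def test_constructed_breakpoint_found(self):
        scales = self._grid()
        stat = np.where(scales <= 100, scales**0.8, 100**0.3 * scales**0.5)
        m = detect_M(ScalingFit(scales=scales, statistic=stat))
        assert m == 100

    def test_pure_power_law_reports_no_crossover(self):
        scales = self._grid()
        m, details = detect_M(
            ScalingFit(scales=scales, statistic=scales**0.7), return_details=True
        )
        assert not details["detected"]
        assert m == scales[-1]

    def test_correlation_cutoff_located_within_factor_two(self):
        """Concatenating independent fGn segments of length 1000 caps the
        correlation duration near the segment length."""
        ms = []
        for seed in range(10):
            segs = [
                gen_fgn(SyntheticSpec(kind="fgn", H=0.85, n=1000, seed=800 + 8 * seed + k)).values
                for k in range(8)
            ]
            curve = rmsf_curve(StepSeries(values=np.concatenate(segs)))
            ms.append(detect_M(curve))
        med = np.median(ms)
        assert 500 <= med <= 2000

    def test_short_curve_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_M(ScalingFit(scales=np.arange(1, 6), statistic=np.ones(5)))

    def test_never_below_smallest_scale(self):
        scales = self._grid()
        stat = np.where(scales <= 20, scales**0.9, 20**0.7 * scales**0.2)
        m = detect_M(ScalingFit(scales=scales, statistic=stat))
        assert m >= scales[0]


class TestScaleInvariance:
    def test_fgn_alpha_independent_of_stride(self):
        s = gen_fgn(SyntheticSpec(kind="fgn", H=0.8, n=8192, seed=21))
        alphas = scale_invariance(s)
        assert set(alphas) == {1, 5, 10, 25}
        vals = np.array(list(alphas.values()))
        assert vals.max() - vals.min() < 0.05

    def test_constant_series_fails(self):
        with pytest.raises(InsufficientDataError):
            scale_invariance(StepSeries(values=np.ones(512)))

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            scale_invariance(StepSeries(values=np.random.default_rng(0).normal(size=64)))


class TestRmsfAnalysis:
    def test_fgn_pipeline_recovers_H(self):
        res = rmsf_analysis(gen_fgn(SyntheticSpec(kind="fgn", H=0.8, n=8192, seed=33)))
        assert res.alpha == pytest.approx(0.8, abs=0.08)
        assert res.m_steps >= res.fit.scales[0]
        assert set(res.alpha_by_delta) == {1, 5, 10, 25}
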