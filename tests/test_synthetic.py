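from __future__ import annotations

import numpy as np
import pytest

from migrastat import (
    SyntheticSpec,
    directionality_ratio,
    fgn_autocovariance,
    gen_amoeba_like,
    gen_ballistic,
    gen_fgn,
    gen_levy_walk,
    gen_persistent_walk,
    generate,
)
from migrastat.exceptions import ParameterError
from migrastat.synthetic import _fgn_hosking

ALL_SPECS = [
    SyntheticSpec(kind="fgn", H=0.7, n=256, seed=11),
    SyntheticSpec(kind="brownian2d", n=256, seed=11),
    SyntheticSpec(kind="ballistic", n=256, seed=11, heading=0.7),
    SyntheticSpec(kind="persistent_walk", persistence=0.9, n=256, seed=11),
    SyntheticSpec(kind="levy_walk", mu=2.0, n=256, seed=11),
    SyntheticSpec(kind="amoeba_like", n=256, seed=11),
]


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.kind)
def test_seed_determinism(spec):
    """Identical spec + seed give bitwise-identical output."""
    a, b = generate(spec), generate(spec)
    va = a.values if hasattr(a, "values") else a.positions
    vb = b.values if hasattr(b, "values") else b.positions
    np.testing.assert_array_equal(va, vb)


class TestFgn:
    def test_white_noise_limit_has_no_lag1_correlation(self):
        s = gen_fgn(SyntheticSpec(kind="fgn", H=0.5, n=4096, seed=1))
        x = s.values
        rho1 = np.mean(x[:-1] * x[1:]) / np.var(x)
        assert abs(rho1) < 3 / np.sqrt(len(x))

    def test_antipersistent_lag1_correlation_is_negative(self):
        # analytic rho1 = 2^{2H-1} - 1 < 0 for H < 0.5
        s = gen_fgn(SyntheticSpec(kind="fgn", H=0.3, n=4096, seed=2))
        x = s.values
        assert np.mean(x[:-1] * x[1:]) < 0

    @pytest.mark.parametrize("H", [0.3, 0.8])
    def test_sample_autocovariance_matches_theory(self, H):
        """Known-mean sample autocovariances at lags 1..5 agree with the
        analytic fGn autocovariance within 3 standard errors (n=8192)."""
        lags = np.arange(1, 6)
        estimates = []
        for seed in range(25):
            x = gen_fgn(SyntheticSpec(kind="fgn", H=H, n=8192, seed=100 + seed)).values
            estimates.append([np.mean(x[:-k] * x[k:]) for k in lags])
        estimates = np.asarray(estimates)
        mean = estimates.mean(axis=0)
        se = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        theory = fgn_autocovariance(H, lags)
        assert np.all(np.abs(mean - theory) < 3 * se + 1e-3)

    def test_unit_variance(self):
        xs = [gen_fgn(SyntheticSpec(kind="fgn", H=0.8, n=4096, seed=s)).values for s in range(10)]
        assert abs(np.concatenate(xs).var() - 1.0) < 0.1

    def test_hosking_fallback_matches_theory(self):
        """The recursive conditional sampler reproduces the same process."""
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(60):
            x = _fgn_hosking(256, 0.8, rng)
            estimates.append([np.mean(x[:-k] * x[k:]) for k in (1, 2)])
        mean = np.mean(estimates, axis=0)
        se = np.std(estimates, axis=0, ddof=1) / np.sqrt(60)
        theory = fgn_autocovariance(0.8, np.array([1, 2]))
        assert np.all(np.abs(mean - theory) < 3 * se + 1e-3)

    def test_rectification_records_affine_transform(self):
        s = gen_fgn(SyntheticSpec(kind="fgn", H=0.7, n=1024, seed=3), rectify=True)
        assert np.all(s.values >= 0)
        assert s.meta["clipped_frac"] < 0.05
        assert {"shift", "scale"} <= set(s.meta)
        assert abs(s.values.mean() - 0.008) < 1e-12

    @pytest.mark.parametrize("H", [0.0, 1.0, -0.2, 1.3, None])
    def test_invalid_H_rejected(self, H):
        with pytest.raises(ParameterError):
            SyntheticSpec(kind="fgn", H=H, n=128, seed=0)


class TestWalkGenerators:
    def test_ballistic_positions_and_dr(self):
        t = gen_ballistic(SyntheticSpec(kind="ballistic", n=100, seed=0))
        np.testing.assert_allclose(t.positions[:, 0], np.arange(100) * 0.008, atol=1e-15)
        np.testing.assert_allclose(t.positions[:, 1], 0, atol=1e-15)
        assert directionality_ratio(t) == pytest.approx(1.0)

    def test_brownian_isotropy(self):
        ends = [
            generate(SyntheticSpec(kind="brownian2d", n=64, seed=s)).positions[-1]
            for s in range(200)
        ]
        mean_end = np.mean(ends, axis=0)
        se = 0.008 * np.sqrt(63) / np.sqrt(200)
        assert np.all(np.abs(mean_end) < 4 * se)

    def test_persistent_heading_correlation(self):
        t = gen_persistent_walk(
            SyntheticSpec(kind="persistent_walk", persistence=0.9, n=4096, seed=5)
        )
        d = t.displacements()
        theta = np.arctan2(d[:, 1], d[:, 0])
        assert np.mean(np.cos(np.diff(theta))) == pytest.approx(0.9, abs=0.02)

    def test_persistence_zero_is_isotropic(self):
        t = gen_persistent_walk(
            SyntheticSpec(kind="persistent_walk", persistence=0.0, n=4096, seed=6)
        )
        d = t.displacements()
        theta = np.arctan2(d[:, 1], d[:, 0])
        # resultant length of uniform headings is O(1/sqrt(n))
        assert np.hypot(np.cos(theta).mean(), np.sin(theta).mean()) < 3 / np.sqrt(len(theta))

    def test_persistence_near_one_is_nearly_ballistic(self):
        t = gen_persistent_walk(
            SyntheticSpec(kind="persistent_walk", persistence=0.9999, n=500, seed=7)
        )
        assert directionality_ratio(t) > 0.95

    def test_persistence_out_of_range(self):
        with pytest.raises(ParameterError):
            SyntheticSpec(kind="persistent_walk", persistence=1.0, n=128, seed=0)

    def test_levy_constant_speed_piecewise_straight(self):
        t = gen_levy_walk(SyntheticSpec(kind="levy_walk", mu=1.5, n=2048, seed=8))
        u = np.linalg.norm(t.displacements(), axis=1)
        np.testing.assert_allclose(u, 0.008, atol=1e-12)

    def test_levy_tail_exponent_orders_diffusivity(self):
        from migrastat import msd_direct

        def mean_beta(mu):
            betas = []
            for s in range(8):
                t = gen_levy_walk(SyntheticSpec(kind="levy_walk", mu=mu, n=4096, seed=50 + s))
                betas.append(msd_direct(t).beta_dc)
            return float(np.mean(betas))

        heavy, light = mean_beta(1.5), mean_beta(3.0)
        assert heavy > 1.3  # strongly super-diffusive
        assert 0.8 < light < 1.45  # near the finite-variance Brownian limit
        assert heavy > light

    def test_levy_mu_out_of_range(self):
        for mu in (1.0, 3.5, None):
            with pytest.raises(ParameterError):
                SyntheticSpec(kind="levy_walk", mu=mu, n=128, seed=0)

    def test_minimum_length_enforced(self):
        with pytest.raises(ParameterError):
            SyntheticSpec(kind="brownian2d", n=32, seed=0)


class TestAmoebaLike:
    def test_default_speed_scale(self):
        speeds = []
        for s in range(10):
            t = gen_amoeba_like(SyntheticSpec(kind="amoeba_like", n=2048, seed=s))
            u = np.linalg.norm(t.displacements(), axis=1)
            speeds.append(u.mean() / t.dt)
        # mean step 0.008 mm per 2 s frame -> 0.004 mm/s (stops shave ~1%)
        assert np.mean(speeds) == pytest.approx(0.004, rel=0.05)

    def test_stop_rate_zero_leaves_only_clipping_zeros(self):
        # with no stop states the only exact zeros come from rectification
        # clipping (the 3-SD shift leaves ~0.1% of the Gaussian tail below 0)
        t = gen_amoeba_like(SyntheticSpec(kind="amoeba_like", n=1024, seed=1, stop_rate=0.0))
        u = np.linalg.norm(t.displacements(), axis=1)
        assert np.mean(u == 0) <= t.meta["clipped_frac"] + 1e-12
        assert t.meta["clipped_frac"] < 0.01

    def test_stop_rate_inserts_stops(self):
        t = gen_amoeba_like(SyntheticSpec(kind="amoeba_like", n=1024, seed=1, stop_rate=0.1))
        u = np.linalg.norm(t.displacements(), axis=1)
        assert np.mean(u == 0) == pytest.approx(0.1, abs=0.04)

    def test_emulates_empirical_regime(self):
        """Defaults produce super-diffusive, persistently correlated walks in
        the empirically observed ranges."""
        from migrastat import msd_direct, rmsf_analysis, to_step_series

        alphas, betas = [], []
        for s in range(6):
            t = gen_amoeba_like(SyntheticSpec(kind="amoeba_like", n=4096, seed=20 + s))
            alphas.append(rmsf_analysis(to_step_series(t)).alpha)
            betas.append(msd_direct(t).beta_dc)
        assert 0.6 < np.mean(alphas) < 0.95
        assert 1.3 < np.mean(betas) <= 2.0
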