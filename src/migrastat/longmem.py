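"""Long-memory estimators: DFA, dispersion-analysis Hurst, and shuffle null.

Detrended fluctuation analysis (DFA) integrates the mean-centered series into
a profile z(t) = Σ (u(k) − <u>), tiles it with non-overlapping boxes of size
n from the series start, removes the least-squares linear trend per box, and
measures the residual fluctuation

    D(n) = sqrt( (1/t_cov) Σ [z(t) − z_n(t)]² )

over the covered samples. Long memory shows as D(n) ~ n^γ, with γ = 0.5 for
white noise and γ ≈ H for fractional Gaussian noise.

Dispersion analysis estimates the Hurst exponent of a stationary series from
the standard deviation of non-overlapping block means: SD(n) = SD(1)·n^{H−1},
so H is one plus the log-log slope. Bins are powers of two starting at n = 2;
bins with fewer than ``min_blocks`` blocks are excluded because the SD of a
handful of block means is biased low enough to corrupt the slope (with the
default cutoff the estimator reproduces the white-noise calibration H ≈ 0.5).

The shuffle null destroys temporal structure while preserving each series'
value distribution: many random permutations per series, re-estimated with
dispersion analysis, build the no-correlation reference ensemble against
which experimental exponents are compared by rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InsufficientDataError, ParameterError
from .io_tracks import StepSeries
from .scaling import ScalingFit, effectively_constant, fit_powerlaw

__all__ = ["NullEnsemble", "dfa", "dispersion_hurst", "shuffle_null", "null_pvalue"]


def _dfa_boxes(n: int, *, n_points: int = 20) -> np.ndarray:
    lo, hi = 4, n // 4
    if hi < lo:
        raise InsufficientDataError(f"series of length {n} too short for DFA")
    return np.unique(np.round(np.logspace(np.log10(lo), np.log10(hi), n_points)).astype(int))


def dfa(
    series: StepSeries,
    box_sizes: np.ndarray | None = None,
    *,
    order: int = 1,
) -> ScalingFit:
    """Detrended fluctuation analysis; returns the D(n) curve with γ fitted.

    ``order`` is the detrending polynomial order (default 1, i.e. a straight
    line per box). Boxes tile the profile from the start; a trailing
    remainder shorter than n is excluded and D(n) is normalized by the
    covered length.
    """
    u = series.values
    n = len(u)
    if box_sizes is None:
        box_sizes = _dfa_boxes(n)
    box_sizes = np.unique(np.asarray(box_sizes, dtype=int))
    if np.any(box_sizes < max(4, order + 2)):
        raise ParameterError("box sizes must be >= 4 (and exceed the detrend order + 1)")
    box_sizes = box_sizes[box_sizes <= n]
    if len(box_sizes) == 0:
        raise InsufficientDataError("no usable box sizes for this series length")

    if effectively_constant(u):
        raise DegenerateInputError(
            "constant series: the profile is linear and fully removed by detrending"
        )
    z = np.cumsum(u - u.mean())
    stats = np.empty(len(box_sizes))
    for i, size in enumerate(box_sizes):
        m = n // size
        boxes = z[: m * size].reshape(m, size).T  # (size, m)
        x = np.arange(size, dtype=float)
        design = np.vander(x, order + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design, boxes, rcond=None)
        resid = boxes - design @ coef
        stats[i] = np.sqrt(np.mean(resid**2))
    curve = ScalingFit(
        scales=box_sizes, statistic=stats, method_tag="dfa", meta={"order": order, "n": n}
    )
    if np.all(stats == 0):
        raise DegenerateInputError(
            "constant series: the profile is linear and fully removed by detrending"
        )
    return fit_powerlaw(curve)


def _dispersion_bins(n: int, *, min_blocks: int, max_bin_frac: float) -> np.ndarray:
    bins = []
    size = 2
    while size <= n * max_bin_frac and n // size >= max(min_blocks, 2):
        bins.append(size)
        size *= 2
    if len(bins) < 3 and min_blocks > 2:
        # short series: relax the cutoff rather than fail outright
        return _dispersion_bins(n, min_blocks=2, max_bin_frac=max_bin_frac)
    if len(bins) < 3:
        raise InsufficientDataError(f"series of length {n} too short for dispersion analysis")
    return np.asarray(bins)


def dispersion_hurst(
    series: StepSeries,
    bins: np.ndarray | None = None,
    *,
    min_blocks: int = 16,
    max_bin_frac: float = 0.5,
) -> ScalingFit:
    """Hurst exponent by dispersion analysis; ``exponent`` holds H.

    SD(n) is the population standard deviation of the means of non-overlapping
    blocks of n consecutive values; H = 1 + slope of log10 SD vs log10 n.
    Default bins are powers of two from 2 up to ``max_bin_frac`` of the
    length, keeping only bins with at least ``min_blocks`` blocks.
    """
    x = series.values
    n = len(x)
    if n < 8:
        raise InsufficientDataError(f"series of length {n} too short (need >= 8)")
    if effectively_constant(x):
        raise DegenerateInputError("constant series: SD(1) = 0, Hurst exponent undefined")
    if bins is None:
        bins = _dispersion_bins(n, min_blocks=min_blocks, max_bin_frac=max_bin_frac)
    bins = np.unique(np.asarray(bins, dtype=int))
    if np.any(bins < 2):
        raise ParameterError("bins must be >= 2")

    stats = np.empty(len(bins))
    for i, size in enumerate(bins):
        m = n // size
        means = x[: m * size].reshape(m, size).mean(axis=1)
        stats[i] = float(means.std())
    curve = ScalingFit(
        scales=bins,
        statistic=stats,
        method_tag="dispersion",
        meta={"sd1": float(x.std()), "min_blocks": min_blocks, "n": n},
    )
    fitted = fit_powerlaw(curve, min_points=3)
    fitted.exponent = float(fitted.exponent) + 1.0  # slope is H - 1
    return fitted


@dataclass
class NullEnsemble:
    """Hurst exponents of shuffled replicates, with the experimental contrast.

    ``h_values`` has one entry per (series, permutation) pair;
    ``experimental_h`` holds the unshuffled estimates; ``comparison_p`` is
    the two-sided rank-sum p-value of experimental vs shuffled exponents.
    """

    h_values: np.ndarray
    n_perm_per_series: int
    mean_h: float
    sd_h: float
    experimental_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    comparison_p: float | None = None
    n_failed: int = 0


def shuffle_null(
    series_list: list[StepSeries],
    n_perm: int = 200,
    seed: int = 0,
    *,
    compare_experimental: bool = True,
    **hurst_kwargs,
) -> NullEnsemble:
    """Permutation null ensemble of dispersion-Hurst exponents.

    Each input series is randomly permuted ``n_perm`` times (each permutation
    preserves the multiset of values) and the Hurst exponent of every
    replicate is estimated. One child seed is derived per (series,
    permutation) pair from the master ``seed``, so any subset of the ensemble
    is reproducible in isolation. Degenerate series are counted in
    ``n_failed`` rather than aborting the ensemble.
    """
    if not series_list:
        raise InsufficientDataError("need at least one series")
    h_values = []
    experimental = []
    n_failed = 0
    for i, series in enumerate(series_list):
        if compare_experimental:
            try:
                experimental.append(dispersion_hurst(series, **hurst_kwargs).exponent)
            except DegenerateInputError:
                n_failed += 1
        for j in range(n_perm):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i, j)))
            shuffled = StepSeries(
                values=rng.permutation(series.values),
                dt=series.dt,
                source_id=f"{series.source_id}-perm{j}",
            )
            try:
                h = dispersion_hurst(shuffled, **hurst_kwargs).exponent
            except DegenerateInputError:
                n_failed += 1
                continue
            if not -0.5 <= h <= 1.5:
                raise ParameterError(f"Hurst estimate {h:.3f} outside the plausible range")
            h_values.append(h)
    h_arr = np.asarray(h_values)
    exp_arr = np.asarray(experimental)
    p = None
    if compare_experimental and len(exp_arr) and len(h_arr):
        p = null_pvalue(exp_arr.tolist(), h_arr.tolist())
    return NullEnsemble(
        h_values=h_arr,
        n_perm_per_series=n_perm,
        mean_h=float(h_arr.mean()) if len(h_arr) else float("nan"),
        sd_h=float(h_arr.std(ddof=1)) if len(h_arr) > 1 else float("nan"),
        experimental_h=exp_arr,
        comparison_p=p,
        n_failed=n_failed,
    )


def null_pvalue(experimental_h: list[float], shuffled_h: list[float]) -> float:
    """Two-sided rank-sum p-value of experimental vs shuffled exponents."""
    from .compare import wilcoxon_ranksum  # deferred: compare also imports longmem

    return wilcoxon_ranksum(experimental_h, shuffled_h).p_value
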