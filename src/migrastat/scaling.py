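"""Log-log power-law fitting shared by all scaling analyses.

Every estimator in this package reduces to the same primitive: a grid of
scales (window length l, box size n, or lag τ), a nonnegative statistic on
that grid (F, D, SD, MSD), and an exponent obtained as the OLS slope of
log10(statistic) against log10(scale). :class:`ScalingFit` carries the curve,
the fitted exponent and its diagnostics; :func:`fit_powerlaw` performs the
fit; :func:`broken_stick` locates a crossover between two power-law regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "ScalingFit",
    "fit_powerlaw",
    "broken_stick",
    "default_scales",
    "effectively_constant",
]


def effectively_constant(x: np.ndarray, rtol: float = 1e-12) -> bool:
    """True when the series varies by less than ``rtol`` of its magnitude.

    Step series derived from exactly regular trajectories (e.g. a ballistic
    walk) are constant only up to floating-point rounding; without this guard
    the scaling estimators would fit pure numerical noise.
    """
    x = np.asarray(x, dtype=float)
    scale = float(np.max(np.abs(x))) if len(x) else 0.0
    return float(np.ptp(x)) <= rtol * max(scale, 1e-300)


@dataclass
class ScalingFit:
    """A (scale, statistic) curve with an optional fitted exponent.

    Zero statistic values are legal in the curve (they arise for degenerate
    inputs) but are excluded from any log-log fit.
    """

    scales: np.ndarray
    statistic: np.ndarray
    method_tag: str = ""
    exponent: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    fit_range: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)
        if self.scales.shape != self.statistic.shape or self.scales.ndim != 1:
            raise ValidationError("scales and statistic must be matching 1D arrays")
        if len(self.scales) and np.any(np.diff(self.scales) <= 0):
            raise ValidationError("scales must be strictly increasing")
        if np.any(self.statistic < 0) or not np.all(np.isfinite(self.statistic)):
            raise ValidationError("statistic values must be finite and nonnegative")

    def predicted(self) -> np.ndarray:
        """Fitted power law evaluated on the scale grid (requires a fit)."""
        if self.exponent is None or self.intercept is None:
            raise ValueError("no fit has been performed")
        return 10.0 ** (self.intercept + self.exponent * np.log10(self.scales))


def default_scales(
    n: int, *, max_fraction: float = 0.25, per_decade: int = 25, dense_upto: int = 10
) -> np.ndarray:
    """Default scale grid: every integer up to ``dense_upto``, then
    log-spaced (≈``per_decade`` points per decade) up to ``n * max_fraction``.

    Dense small scales anchor the fit; logarithmic spacing bounds the cost at
    large scales.
    """
    top = int(n * max_fraction)
    if top < 2:
        raise InsufficientDataError(f"series of length {n} is too short for a scale grid")
    small = np.arange(1, min(dense_upto, top) + 1)
    if top <= dense_upto:
        return small.astype(int)
    n_pts = max(2, int(np.log10(top / dense_upto) * per_decade))
    coarse = np.round(np.logspace(np.log10(dense_upto), np.log10(top), n_pts)).astype(int)
    return np.unique(np.concatenate([small, coarse]))


def fit_powerlaw(
    curve: ScalingFit,
    fit_range: tuple[float, float] | None = None,
    *,
    min_points: int = 4,
) -> ScalingFit:
    """OLS fit of log10(statistic) vs log10(scale); returns a new fit object.

    Points with zero statistic (log undefined) are excluded. Fewer than
    ``min_points`` usable points raise :class:`InsufficientDataError`.
    """
    lo, hi = fit_range if fit_range is not None else (curve.scales[0], curve.scales[-1])
    mask = (curve.scales >= lo) & (curve.scales <= hi) & (curve.statistic > 0)
    if int(mask.sum()) < min_points:
        raise InsufficientDataError(
            f"power-law fit needs >= {min_points} positive points in "
            f"[{lo}, {hi}]; got {int(mask.sum())}"
        )
    x = np.log10(curve.scales[mask])
    y = np.log10(curve.statistic[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return replace(
        curve,
        exponent=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        fit_range=(float(lo), float(hi)),
    )


def _hinge_rss(x: np.ndarray, y: np.ndarray, knot: float) -> float:
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - knot)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.sum((y - design @ coef) ** 2))


def broken_stick(
    x: Sequence[float], y: Sequence[float], *, min_segment: int = 3
) -> tuple[int, float]:
    """Two-segment continuous (hinge) regression over candidate knots at the
    data points.

    Returns ``(knot_index, improvement)`` where ``improvement`` is the
    fractional reduction in residual sum of squares relative to a single
    straight line. Knots leaving fewer than ``min_segment`` points on either
    side are not considered; ties are broken toward the larger knot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 * min_segment:
        raise InsufficientDataError("too few points for a two-segment fit")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss1 = float(np.sum((y - design @ coef) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if rss1 <= 1e-12 * max(ss_tot, 1e-300):
        # a single line already fits to numerical precision
        return len(x) - min_segment - 1, 0.0
    best_k, best_rss = min_segment - 1, np.inf
    for k in range(min_segment - 1, len(x) - min_segment):
        rss = _hinge_rss(x, y, x[k])
        if rss <= best_rss:  # <= keeps the larger knot on ties
            best_k, best_rss = k, rss
    improvement = 1.0 - best_rss / rss1 if rss1 > 0 else 0.0
    return best_k, float(improvement)
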