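"""Root-mean-square fluctuation (rmsf) analysis of move-step series.

For a step series u(t), the net displacement after l steps is the cumulative
sum y(l) = Σ_{i≤l} u(i), and the rmsf is

    F(l) = sqrt( <Δy(l)²> − <Δy(l)>² ),   Δy(l) = y(l + l₀) − y(l₀),

with the brackets averaging over window offsets l₀ (stride Δl₀, default 1 —
all possible offsets). Long-range correlation shows as a power law
F(l) ~ l^α: α = 0.5 for uncorrelated steps, α > 0.5 for persistent ones.

Two companion quantities are derived from the F(l) curve:

* the long-range-correlation duration M — the largest window length before
  the log-log curve departs from the initial power law, located by a
  two-segment (hinge) regression and rounded to the nearest 100 steps;
* scale invariance of α across offset strides Δl₀ ∈ {1, 5, 10, 25} — for a
  genuinely scale-invariant series the exponent does not depend on Δl₀.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, ParameterError
from .io_tracks import StepSeries
from .scaling import (
    ScalingFit,
    broken_stick,
    default_scales,
    effectively_constant,
    fit_powerlaw,
)

__all__ = [
    "RmsfResult",
    "rmsf_curve",
    "fit_alpha",
    "detect_M",
    "scale_invariance",
    "rmsf_analysis",
    "DEFAULT_DELTAS",
]

#: Offset strides used for the scale-invariance check.
DEFAULT_DELTAS = (1, 5, 10, 25)


@dataclass
class RmsfResult:
    """Full rmsf analysis of one series: α fit, correlation duration M, and
    the α-by-stride map; ``crossover_detected`` records whether M came from a
    genuine breakpoint or defaulted to the largest scale."""

    fit: ScalingFit
    m_steps: int
    alpha_by_delta: dict[int, float]
    crossover_detected: bool

    @property
    def alpha(self) -> float:
        return self.fit.exponent


def rmsf_curve(
    series: StepSeries,
    scales: np.ndarray | None = None,
    delta_l0: int = 1,
) -> ScalingFit:
    """F(l) over a grid of window lengths (curve only; exponent unset).

    For each l, Δy(l) is evaluated at offsets l₀ = 0, Δl₀, 2Δl₀, … with
    l + l₀ ≤ length, and F(l) is the (population) standard deviation of
    those values. Scales admitting fewer than two offsets are dropped with a
    warning; if none survive, :class:`InsufficientDataError` is raised.
    """
    if delta_l0 < 1 or int(delta_l0) != delta_l0:
        raise ParameterError(f"delta_l0 must be a positive integer, got {delta_l0}")
    u = series.values
    n = len(u)
    if scales is None:
        scales = default_scales(n)
    scales = np.unique(np.asarray(scales, dtype=int))
    if np.any(scales < 1):
        raise ParameterError("scales must be positive integers")
    constant = effectively_constant(u)
    y = np.concatenate([[0.0], np.cumsum(u)])

    kept, stats = [], []
    for l in scales:
        offsets = np.arange(0, n - l + 1, delta_l0)
        if len(offsets) < 2:
            warnings.warn(
                f"scale l={l} admits fewer than 2 offsets at stride {delta_l0}; dropped",
                stacklevel=2,
            )
            continue
        dy = y[offsets + l] - y[offsets]
        kept.append(l)
        stats.append(0.0 if constant else float(dy.std()))
    if not kept:
        raise InsufficientDataError(
            f"no scale admits 2 offsets for a series of length {n} at stride {delta_l0}"
        )
    return ScalingFit(
        scales=np.asarray(kept),
        statistic=np.asarray(stats),
        method_tag="rmsf",
        meta={"delta_l0": int(delta_l0), "n": n},
    )


def fit_alpha(curve: ScalingFit, fit_range: tuple[float, float] | None = None) -> ScalingFit:
    """Fit α as the log-log OLS slope of F(l) over ``fit_range``.

    F(l) = 0 points are excluded; fewer than 4 usable points raise
    :class:`InsufficientDataError`.
    """
    return fit_powerlaw(curve, fit_range)


def detect_M(
    curve: ScalingFit,
    *,
    min_improvement: float = 0.05,
    round_to: int = 100,
    return_details: bool = False,
):
    """Long-range-correlation duration M from the F(l) crossover.

    A two-segment continuous regression is fitted in log-log space; if it
    improves the single-line residual sum of squares by at least
    ``min_improvement`` (fraction), M is the breakpoint scale rounded to the
    nearest ``round_to`` steps (clamped into the scale grid). Otherwise no
    crossover is detectable and M is the largest scale in the grid.
    """
    mask = curve.statistic > 0
    scales = curve.scales[mask]
    stats = curve.statistic[mask]
    if len(scales) < 6 or scales[-1] / scales[0] < 10:
        raise InsufficientDataError("curve must span at least one decade of scales")
    x, y = np.log10(scales), np.log10(stats)
    k, improvement = broken_stick(x, y)
    detected = improvement >= min_improvement
    if detected:
        breakpoint_scale = scales[k]
        m = int(np.floor(breakpoint_scale / round_to + 0.5)) * round_to
        # a breakpoint below round_to/2 would round to zero; keep M at least
        # one rounding unit (and inside the scale grid)
        m = int(np.clip(m, min(round_to, scales[-1]), scales[-1]))
        m = int(max(m, scales[0]))
    else:
        m = int(scales[-1])
    if return_details:
        return m, {
            "detected": detected,
            "improvement": float(improvement),
            "breakpoint_scale": float(scales[k]),
        }
    return m


def _default_fit_range(
    n: int, m_steps: int, detected: bool, min_scale: float
) -> tuple[float, float]:
    # pre-crossover regime when a crossover exists, else the first tenth
    return (min_scale, float(m_steps) if detected else max(n / 10.0, 10 * min_scale))


def scale_invariance(
    series: StepSeries,
    deltas: tuple[int, ...] = DEFAULT_DELTAS,
    scales: np.ndarray | None = None,
    fit_range: tuple[float, float] | None = None,
) -> dict[int, float]:
    """α for each offset stride Δl₀, using one common fit range.

    When ``fit_range`` is None it is derived once from the Δl₀ = 1 curve
    (pre-crossover regime, as for the main α fit) and reused for all strides.
    """
    n = len(series.values)
    if n < 4 * max(deltas):
        raise InsufficientDataError(
            f"series of length {n} too short for stride {max(deltas)}"
        )
    if fit_range is None:
        base = rmsf_curve(series, scales=scales, delta_l0=1)
        m_steps, details = detect_M(base, return_details=True)
        fit_range = _default_fit_range(n, m_steps, details["detected"], base.scales[0])
    out: dict[int, float] = {}
    for d in deltas:
        curve = rmsf_curve(series, scales=scales, delta_l0=d)
        out[int(d)] = fit_alpha(curve, fit_range).exponent
    return out


def rmsf_analysis(
    series: StepSeries,
    scales: np.ndarray | None = None,
    deltas: tuple[int, ...] = DEFAULT_DELTAS,
    fit_range: tuple[float, float] | None = None,
) -> RmsfResult:
    """Complete rmsf analysis: F(l) curve, crossover duration M, α over the
    pre-crossover range, and the scale-invariance map."""
    curve = rmsf_curve(series, scales=scales, delta_l0=1)
    m_steps, details = detect_M(curve, return_details=True)
    if fit_range is None:
        fit_range = _default_fit_range(
            len(series.values), m_steps, details["detected"], curve.scales[0]
        )
    fit = fit_alpha(curve, fit_range)
    alpha_by_delta = scale_invariance(series, deltas=deltas, scales=scales, fit_range=fit_range)
    return RmsfResult(
        fit=fit,
        m_steps=m_steps,
        alpha_by_delta=alpha_by_delta,
        crossover_detected=details["detected"],
    )
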