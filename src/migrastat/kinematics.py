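"""Kinematic metrics: directionality ratio, average speed, total distance.

The directionality ratio DR = d/δ compares the net Euclidean displacement d
(start to endpoint) with the path length δ (sum of step magnitudes): 1 for a
perfectly straight path, 0 for a path returning to its start. Besides the
global value, a profile of DR at endpoints every 200 time points (400 s at
dt = 2) up to 3800 points reproduces the heatmap layout used to compare
cells over increasing horizons.

Average speed is the mean step magnitude divided by the frame interval;
total distance is the path length over a fixed comparison horizon (130 min,
the duration of the shortest usable track) so cells recorded for different
times remain comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InsufficientDataError
from .io_tracks import Trajectory2D

__all__ = [
    "KinematicsResult",
    "directionality_ratio",
    "dr_profile",
    "average_speed",
    "total_distance",
    "kinematics_summary",
]


@dataclass
class KinematicsResult:
    """Kinematic summary of one trajectory."""

    dr_global: float
    dr_profile: np.ndarray
    profile_endpoints: np.ndarray
    as_mm_per_s: float
    td_mm: float


def directionality_ratio(traj: Trajectory2D, endpoint: int | None = None) -> float:
    """DR = d/δ up to ``endpoint`` (position index; default the last point).

    Raises :class:`DegenerateInputError` when the path length δ is zero.
    """
    if endpoint is None:
        endpoint = traj.n_points - 1
    endpoint = int(endpoint)
    if not 2 <= endpoint <= traj.n_points - 1:
        raise InsufficientDataError(
            f"endpoint must lie in [2, {traj.n_points - 1}], got {endpoint}"
        )
    d = float(np.hypot(*(traj.positions[endpoint] - traj.positions[0])))
    delta = float(traj.step_lengths()[:endpoint].sum())
    if delta == 0.0:
        raise DegenerateInputError("no movement up to the endpoint: path length is zero")
    return d / delta


def dr_profile(
    traj: Trajectory2D, start: int = 200, step: int = 200, stop: int = 3800
) -> tuple[np.ndarray, np.ndarray]:
    """DR at endpoints ``start, start+step, …, stop`` time points.

    Endpoints beyond the trajectory are omitted, so a 3900-point track yields
    the full 19-value profile while shorter tracks yield fewer values.
    Returns ``(endpoints, dr_values)``.
    """
    if traj.n_points <= start:
        raise InsufficientDataError(
            f"trajectory of {traj.n_points} points shorter than the first endpoint {start}"
        )
    endpoints = np.arange(start, stop + 1, step)
    endpoints = endpoints[endpoints <= traj.n_points - 1]
    values = np.array([directionality_ratio(traj, int(e)) for e in endpoints])
    return endpoints, values


def average_speed(traj: Trajectory2D) -> float:
    """Mean step magnitude divided by the frame interval, in mm/s."""
    return float(traj.step_lengths().mean()) / traj.dt


def total_distance(traj: Trajectory2D, horizon_minutes: float = 130.0) -> float:
    """Path length over the first ``horizon_minutes`` of the track, in mm.

    A track shorter than the horizon is summed over its available length
    with a warning (recording-length inclusion criteria normally prevent
    this).
    """
    n_steps = int(horizon_minutes * 60.0 / traj.dt)
    u = traj.step_lengths()
    if len(u) < n_steps:
        warnings.warn(
            f"trajectory '{traj.cell_id}' covers {len(u)} steps, shorter than the "
            f"{n_steps}-step horizon; total distance computed over the available length",
            stacklevel=2,
        )
    return float(u[:n_steps].sum())


def kinematics_summary(
    traj: Trajectory2D,
    *,
    profile_start: int = 200,
    profile_step: int = 200,
    profile_stop: int = 3800,
    horizon_minutes: float = 130.0,
) -> KinematicsResult:
    """Global DR, DR profile, average speed and total distance of one track."""
    endpoints, profile = dr_profile(traj, profile_start, profile_step, profile_stop)
    return KinematicsResult(
        dr_global=directionality_ratio(traj),
        dr_profile=profile,
        profile_endpoints=endpoints,
        as_mm_per_s=average_speed(traj),
        td_mm=total_distance(traj, horizon_minutes),
    )
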