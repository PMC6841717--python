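"""Model/Results interface tying the estimator pipeline together.

:class:`CellMigrationModel` is built from one trajectory (directly, or from
a tracked-spots DataFrame via :meth:`CellMigrationModel.from_dataframe`) plus
the analysis parameters; :meth:`CellMigrationModel.fit` runs every stage —
move-step extraction, rmsf (α, M, scale invariance), DFA (γ), dispersion
Hurst (H), MSD (β direct and RGO), kinematics (DR, AS, TD) — and returns a
:class:`CellMigrationResults` carrying the estimates, the underlying scaling
curves, per-stage failures, and a ``summary()`` table.

Stages that cannot produce an estimate for a particular cell (a stationary
track, a series too short for the requested scales) record the failure and
leave the corresponding metric unset instead of aborting the pipeline.
The analysis path contains no randomness: fitting the same trajectory twice
yields identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import diffusion, fluctuation, kinematics, longmem
from .compare import CellMetrics
from .exceptions import DegenerateInputError, InsufficientDataError
from .io_tracks import StepSeries, Trajectory2D, to_step_series
from .scaling import ScalingFit

__all__ = ["CellMigrationModel", "CellMigrationResults"]

_RECOVERABLE = (DegenerateInputError, InsufficientDataError)


@dataclass
class CellMigrationResults:
    """Fitted estimates and diagnostics for one cell."""

    trajectory: Trajectory2D
    steps: StepSeries
    params: dict[str, Any]
    rmsf: fluctuation.RmsfResult | None = None
    dfa_fit: ScalingFit | None = None
    dispersion_fit: ScalingFit | None = None
    msd: diffusion.MSDResult | None = None
    kin: kinematics.KinematicsResult | None = None
    failures: dict[str, str] = field(default_factory=dict)

    # -- scalar accessors -------------------------------------------------
    @property
    def alpha(self) -> float | None:
        return self.rmsf.alpha if self.rmsf else None

    @property
    def corr_duration_steps(self) -> int | None:
        return self.rmsf.m_steps if self.rmsf else None

    @property
    def gamma(self) -> float | None:
        return self.dfa_fit.exponent if self.dfa_fit else None

    @property
    def hurst(self) -> float | None:
        return self.dispersion_fit.exponent if self.dispersion_fit else None

    @property
    def beta_dc(self) -> float | None:
        return self.msd.beta_dc if self.msd else None

    @property
    def beta_rgo(self) -> float | None:
        return self.msd.rgo_beta if self.msd else None

    @property
    def dr(self) -> float | None:
        return self.kin.dr_global if self.kin else None

    @property
    def avg_speed(self) -> float | None:
        return self.kin.as_mm_per_s if self.kin else None

    @property
    def total_dist(self) -> float | None:
        return self.kin.td_mm if self.kin else None

    def to_metrics(self) -> CellMetrics:
        """Flatten into one summary-table row."""
        return CellMetrics(
            cell_id=self.trajectory.cell_id,
            group=self.trajectory.group,
            alpha=self.alpha,
            m_steps=self.corr_duration_steps,
            gamma=self.gamma,
            beta_dc=self.beta_dc,
            beta_rgo=self.beta_rgo,
            dr=self.dr,
            as_mm_per_s=self.avg_speed,
            td_mm=self.total_dist,
        )

    def summary(self) -> str:
        """Human-readable summary of the fitted metrics."""
        traj = self.trajectory
        lines = [
            "          Cell Migration Trajectory Analysis",
            "=" * 58,
            f"cell_id: {traj.cell_id:<24s} group: {traj.group or '-'}",
            f"points:  {traj.n_points:<24d} dt:    {traj.dt:g} s",
            f"span:    {traj.duration_s / 60.0:.1f} min",
            "-" * 58,
        ]

        def row(label: str, value, fmt: str = "{:.3f}", extra: str = "") -> str:
            if value is None:
                return f"{label:<34s}{'--':>12s}"
            return f"{label:<34s}{fmt.format(value):>12s}  {extra}".rstrip()

        lines.append(row("rmsf exponent (alpha)", self.alpha))
        if self.rmsf is not None:
            lines.append(
                row(
                    "correlation duration (M)",
                    float(self.rmsf.m_steps),
                    "{:.0f}",
                    "steps" + ("" if self.rmsf.crossover_detected else " (no crossover)"),
                )
            )
            spread = (
                max(self.rmsf.alpha_by_delta.values()) - min(self.rmsf.alpha_by_delta.values())
            )
            lines.append(row("alpha spread across strides", spread, "{:.4f}"))
        else:
            lines.append(row("correlation duration (M)", None))
        lines.append(row("DFA exponent (gamma)", self.gamma))
        lines.append(row("dispersion Hurst (H)", self.hurst))
        lines.append(row("MSD exponent, direct (beta)", self.beta_dc))
        lines.append(row("MSD exponent, RGO (beta)", self.beta_rgo))
        lines.append(row("directionality ratio (DR)", self.dr))
        lines.append(row("average speed (AS)", self.avg_speed, "{:.5f}", "mm/s"))
        lines.append(row("total distance (TD)", self.total_dist, "{:.2f}", "mm"))
        if self.failures:
            lines.append("-" * 58)
            for stage, msg in self.failures.items():
                lines.append(f"[{stage}] {msg}")
        lines.append("=" * 58)
        return "\n".join(lines)


class CellMigrationModel:
    """Scaling/diffusion/kinematics analysis of one cell trajectory.

    Parameters mirror the individual estimator functions; the defaults are
    the package defaults documented there. ``fit()`` is deterministic.
    """

    def __init__(
        self,
        trajectory: Trajectory2D,
        *,
        scales: np.ndarray | None = None,
        rmsf_deltas: tuple[int, ...] = fluctuation.DEFAULT_DELTAS,
        rmsf_fit_range: tuple[float, float] | None = None,
        dfa_box_sizes: np.ndarray | None = None,
        dfa_order: int = 1,
        dispersion_min_blocks: int = 16,
        msd_definition: str = "radial",
        tau_max: int | None = None,
        rgo_window: int = 1000,
        rgo_n_set: tuple[int, ...] = diffusion.DEFAULT_N_SET,
        rgo_p_grid: np.ndarray | None = None,
        profile_start: int = 200,
        profile_step: int = 200,
        profile_stop: int = 3800,
        horizon_minutes: float = 130.0,
    ) -> None:
        self.trajectory = trajectory
        self.params: dict[str, Any] = {
            "scales": scales,
            "rmsf_deltas": tuple(rmsf_deltas),
            "rmsf_fit_range": rmsf_fit_range,
            "dfa_box_sizes": dfa_box_sizes,
            "dfa_order": dfa_order,
            "dispersion_min_blocks": dispersion_min_blocks,
            "msd_definition": msd_definition,
            "tau_max": tau_max,
            "rgo_window": rgo_window,
            "rgo_n_set": tuple(rgo_n_set),
            "rgo_p_grid": rgo_p_grid,
            "profile_start": profile_start,
            "profile_step": profile_step,
            "profile_stop": profile_stop,
            "horizon_minutes": horizon_minutes,
        }

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        cell_id: str = "cell",
        x: str = "POSITION_X",
        y: str = "POSITION_Y",
        frame: str = "FRAME",
        dt: float = 2.0,
        scale: float = 1.0,
        group: str | None = None,
        **params,
    ) -> "CellMigrationModel":
        """Build a model from a tracked-spots DataFrame (one cell)."""
        sub = df.sort_values(frame, kind="mergesort")
        positions = sub[[x, y]].to_numpy(dtype=float) * scale
        traj = Trajectory2D(cell_id=cell_id, positions=positions, dt=dt, group=group)
        return cls(traj, **params)

    def fit(self) -> CellMigrationResults:
        """Run every analysis stage; recoverable stage failures are recorded
        in ``results.failures`` instead of raised."""
        p = self.params
        steps = to_step_series(self.trajectory)
        res = CellMigrationResults(trajectory=self.trajectory, steps=steps, params=dict(p))

        try:
            res.rmsf = fluctuation.rmsf_analysis(
                steps, scales=p["scales"], deltas=p["rmsf_deltas"], fit_range=p["rmsf_fit_range"]
            )
        except _RECOVERABLE as exc:
            res.failures["rmsf"] = str(exc)

        try:
            res.dfa_fit = longmem.dfa(steps, box_sizes=p["dfa_box_sizes"], order=p["dfa_order"])
        except _RECOVERABLE as exc:
            res.failures["dfa"] = str(exc)

        try:
            res.dispersion_fit = longmem.dispersion_hurst(
                steps, min_blocks=p["dispersion_min_blocks"]
            )
        except _RECOVERABLE as exc:
            res.failures["dispersion"] = str(exc)

        try:
            res.msd = diffusion.msd_analysis(
                self.trajectory,
                tau_max=p["tau_max"],
                definition=p["msd_definition"],
                window=p["rgo_window"],
                n_set=p["rgo_n_set"],
                p_grid=p["rgo_p_grid"],
            )
        except _RECOVERABLE as exc:
            res.failures["msd"] = str(exc)

        try:
            res.kin = kinematics.kinematics_summary(
                self.trajectory,
                profile_start=p["profile_start"],
                profile_step=p["profile_step"],
                profile_stop=p["profile_stop"],
                horizon_minutes=p["horizon_minutes"],
            )
        except _RECOVERABLE as exc:
            res.failures["kinematics"] = str(exc)

        return res
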