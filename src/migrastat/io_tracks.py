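"""Trajectory data model and plain-text I/O.

A tracked cell is represented by :class:`Trajectory2D` — an ordered sequence
of (x, y) positions in millimetres sampled at a fixed frame interval ``dt``
(2 s in the reference experiments). The one-dimensional signal all
correlation analyses operate on is the *move-step series* u(t): the Euclidean
displacement magnitude between consecutive frames, held in
:class:`StepSeries`.

Input tables are TrackMate-export-style CSV (``TRACK_ID``, ``POSITION_X``,
``POSITION_Y``, ``FRAME``; extra columns ignored) or any CSV with an explicit
column mapping. Coordinates are converted to mm through a caller-supplied
scale factor; no recentering happens at read time — the diffusion analysis
recenters explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    GapWarning,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "Trajectory2D",
    "StepSeries",
    "read_track_table",
    "write_track_table",
    "to_step_series",
    "read_step_series",
    "write_step_series",
    "write_metrics_table",
    "read_metrics_table",
    "TRACKMATE_COLUMNS",
]

#: Default column names of a TrackMate spots export.
TRACKMATE_COLUMNS: Mapping[str, str] = {
    "track_id": "TRACK_ID",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "frame": "FRAME",
}

#: Column order of the per-cell metrics table (mirrors the study's summary
#: tables, prefixed by identification columns).
METRICS_COLUMNS = (
    "cell_id",
    "group",
    "alpha",
    "m_steps",
    "gamma",
    "beta_dc",
    "beta_rgo",
    "dr",
    "as_mm_per_s",
    "td_mm",
)


@dataclass
class Trajectory2D:
    """Time-ordered 2D positions of one tracked cell.

    Parameters
    ----------
    cell_id : str
        Label of the track (one cell per track).
    positions : (N, 2) array of float
        Absolute positions in mm, one row per frame.
    dt : float
        Frame interval in seconds (default 2).
    group : str, optional
        Experimental group label, e.g. ``"non-enucleated"``.
    meta : dict
        Free-form provenance (generator spec, RNG algorithm, ...).
    """

    cell_id: str
    positions: np.ndarray
    dt: float = 2.0
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError(
                f"positions must be an (N, 2) array, got shape {self.positions.shape}"
            )
        if len(self.positions) < 2:
            raise InsufficientDataError(
                f"trajectory '{self.cell_id}' needs at least 2 positions, "
                f"got {len(self.positions)}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError(f"trajectory '{self.cell_id}' has non-finite coordinates")
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")

    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def duration_s(self) -> float:
        """Total recorded time span in seconds."""
        return (self.n_points - 1) * self.dt

    def displacements(self) -> np.ndarray:
        """Per-frame displacement vectors, shape (N-1, 2)."""
        return np.diff(self.positions, axis=0)

    def step_lengths(self) -> np.ndarray:
        """Per-frame displacement magnitudes u(t), shape (N-1,)."""
        d = self.displacements()
        return np.hypot(d[:, 0], d[:, 1])


@dataclass
class StepSeries:
    """A move-step magnitude series u(t) (or a synthetic stand-in).

    Values derived from a trajectory are nonnegative displacement magnitudes
    in mm per frame; synthetic fractional Gaussian noise may be signed (the
    rectifying affine transform, when applied, is recorded in ``meta``).
    """

    values: np.ndarray
    dt: float = 2.0
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("step series values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("step series contains non-finite values")
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return len(self.values)


def to_step_series(traj: Trajectory2D) -> StepSeries:
    """Move-step series u(t) of a trajectory: u[t] = |P(t+1) - P(t)|.

    The result has length N-1 for an N-point trajectory.
    """
    if traj.n_points < 2:  # pragma: no cover - enforced by Trajectory2D
        raise InsufficientDataError("need at least 2 positions")
    return StepSeries(values=traj.step_lengths(), dt=traj.dt, source_id=traj.cell_id)


def _resolve_columns(
    df: pd.DataFrame, dialect: str, column_map: Mapping[str, str] | None
) -> Mapping[str, str]:
    if dialect == "trackmate":
        cols = dict(TRACKMATE_COLUMNS)
        if column_map:
            cols.update(column_map)
    elif dialect == "generic":
        if not column_map:
            raise ConfigurationError("generic dialect requires an explicit column_map")
        cols = dict(column_map)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    for key in ("track_id", "x", "y", "frame"):
        if key not in cols:
            raise ConfigurationError(f"column_map is missing the {key!r} entry")
        if cols[key] not in df.columns:
            raise ConfigurationError(
                f"required column {cols[key]!r} (for {key!r}) not found in file"
            )
    return cols


def read_track_table(
    path: str | Path,
    dialect: str = "trackmate",
    column_map: Mapping[str, str] | None = None,
    *,
    scale: float = 1.0,
    dt: float = 2.0,
    groups: Mapping[str, str] | None = None,
) -> list[Trajectory2D]:
    """Read a tracked-trajectory CSV into one :class:`Trajectory2D` per track.

    Parameters
    ----------
    path : path
        CSV file with a header row.
    dialect : {"trackmate", "generic"}
        ``trackmate`` expects TRACK_ID/POSITION_X/POSITION_Y/FRAME columns;
        ``generic`` requires ``column_map``.
    column_map : mapping, optional
        Maps the keys ``track_id``, ``x``, ``y``, ``frame`` to column names
        in the file (overrides the dialect defaults).
    scale : float
        Multiplicative pixel-to-mm conversion applied to coordinates. The
        deposited data's calibration is not bundled; default 1.0.
    dt : float
        Frame interval in seconds.
    groups : mapping, optional
        track id (as string) -> group label.

    Rows are sorted by frame within each track. Duplicate frames within a
    track raise :class:`ValidationError`; gaps larger than one frame emit a
    :class:`GapWarning` and the step spans the gap (the reference experiments
    sample continuously, so gaps indicate tracking faults).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    if df.empty:
        raise EmptyInputError(f"{path} contains a header but no rows")
    cols = _resolve_columns(df, dialect, column_map)

    trajectories: list[Trajectory2D] = []
    for track_id, sub in df.groupby(cols["track_id"], sort=True):
        sub = sub.sort_values(cols["frame"], kind="mergesort")
        frames = sub[cols["frame"]].to_numpy()
        if len(frames) != len(np.unique(frames)):
            raise ValidationError(f"track {track_id!r} has duplicate frames")
        gaps = np.diff(frames)
        if np.any(gaps > 1):
            warnings.warn(
                f"track {track_id!r} has {int(np.sum(gaps > 1))} frame gap(s); "
                "steps span the gaps",
                GapWarning,
                stacklevel=2,
            )
        positions = sub[[cols["x"], cols["y"]]].to_numpy(dtype=float) * scale
        cid = str(track_id)
        trajectories.append(
            Trajectory2D(
                cell_id=cid,
                positions=positions,
                dt=dt,
                group=groups.get(cid) if groups else None,
            )
        )
    return trajectories


def write_track_table(trajs: Sequence[Trajectory2D], path: str | Path) -> Path:
    """Write trajectories as a TrackMate-style CSV readable by
    :func:`read_track_table`."""
    path = Path(path)
    frames = []
    for traj in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "TRACK_ID": traj.cell_id,
                    "POSITION_X": traj.positions[:, 0],
                    "POSITION_Y": traj.positions[:, 1],
                    "FRAME": np.arange(traj.n_points),
                }
            )
        )
    if not frames:
        raise EmptyInputError("no trajectories to write")
    # %.17g round-trips IEEE doubles exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return path


def write_step_series(series: StepSeries, path: str | Path) -> Path:
    """Write a step series as a single-column CSV (header ``u``)."""
    path = Path(path)
    pd.DataFrame({"u": series.values}).to_csv(path, index=False, float_format="%.17g")
    return path


def read_step_series(path: str | Path, dt: float = 2.0, source_id: str = "") -> StepSeries:
    """Read a single-column (``u``) CSV written by :func:`write_step_series`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    if "u" not in df.columns:
        raise ConfigurationError("step-series file must have a 'u' column")
    return StepSeries(values=df["u"].to_numpy(dtype=float), dt=dt, source_id=source_id or path.stem)


def _row_dict(row) -> dict:
    if dataclasses.is_dataclass(row):
        return dataclasses.asdict(row)
    if hasattr(row, "to_dict"):
        return row.to_dict()
    return dict(vars(row))


def write_metrics_table(
    rows: Sequence,
    path: str | Path,
    *,
    float_format: str = "%.6g",
    config: Mapping | None = None,
) -> Path:
    """Write per-cell metrics as TSV (one row per cell, summary-table column
    order), optionally with a JSON sidecar holding the run configuration.

    ``rows`` may be :class:`~migrastat.compare.CellMetrics` instances or any
    objects exposing the metric fields. The sidecar is written next to the
    table as ``<path>.config.json``.
    """
    if not rows:
        raise EmptyInputError("no metric rows to write")
    path = Path(path)
    records = [_row_dict(r) for r in rows]
    df = pd.DataFrame.from_records(records)
    ordered = [c for c in METRICS_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df = df[ordered + extra]
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    if config is not None:
        sidecar = path.with_name(path.name + ".config.json")
        sidecar.write_text(json.dumps(dict(config), indent=2, default=str))
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics TSV written by :func:`write_metrics_table`."""
    return pd.read_csv(Path(path), sep="\t")
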