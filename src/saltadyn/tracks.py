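"""Trajectory ingestion and per-cell kinematics.

Trajectories are time-stamped positions of single migrating cells (internally
seconds and micrometres; speeds are reported in µm/h, the unit used throughout
the neuroblast-migration literature).  Analysis is 2D by default because the
source movies are per-wavelength maximum-intensity projections; a 3D switch is
available for track tables that carry z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SpeedTrace",
    "TrackFormatError",
    "load_tracks",
    "instantaneous_speed",
    "net_displacement",
    "path_length",
]

log = logging.getLogger(__name__)

SECONDS_PER_HOUR = 3600.0


class TrackFormatError(ValueError):
    """Malformed track table (duplicate timestamps, non-monotonic time, ...)."""


@dataclass
class Trajectory:
    """Time-stamped positions of one cell.

    Parameters
    ----------
    cell_id : str
        Identifier of the tracked cell.
    t : ndarray
        Acquisition times in seconds, strictly increasing, length >= 2.
    x, y : ndarray
        Positions in µm.
    z : ndarray, optional
        Axial position in µm; ignored by 2D kinematics unless ``use_z``.
    source : str
        Free-text provenance (file name, generator, ...).
    """

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        if self.t.size < 2:
            raise ValueError(f"trajectory {self.cell_id!r}: need >= 2 points")
        if self.t.shape != self.x.shape or self.t.shape != self.y.shape:
            raise ValueError(f"trajectory {self.cell_id!r}: t/x/y length mismatch")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.x)) or not np.all(
            np.isfinite(self.y)
        ):
            raise ValueError(f"trajectory {self.cell_id!r}: non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise TrackFormatError(
                f"trajectory {self.cell_id!r}: time not strictly increasing"
            )

    def __len__(self) -> int:
        return self.t.size

    def positions(self, use_z: bool = False) -> np.ndarray:
        """(n, 2) or (n, 3) position array in µm."""
        cols = [self.x, self.y]
        if use_z:
            if self.z is None:
                raise ValueError(f"trajectory {self.cell_id!r} has no z column")
            cols.append(self.z)
        return np.column_stack(cols)


@dataclass
class SpeedTrace:
    """Instantaneous speed between consecutive frames of one trajectory.

    ``t_mid`` are interval midpoints (s), ``v`` speeds in µm/h.  ``t_edges``
    (length n+1) carries the original frame times when known, so that phase
    segmentation can report intervals on the movie's own timeline.
    """

    cell_id: str
    t_mid: np.ndarray
    v: np.ndarray
    t_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t_mid.shape != self.v.shape:
            raise ValueError("t_mid and v must have equal length")
        if np.any(self.v < 0):
            raise ValueError("speeds must be non-negative")
        if self.t_edges is not None:
            self.t_edges = np.asarray(self.t_edges, dtype=float)
            if self.t_edges.size != self.v.size + 1:
                raise ValueError("t_edges must have length len(v)+1")

    def __len__(self) -> int:
        return self.v.size

    def edges(self) -> np.ndarray:
        """Frame-time edges; reconstructed from midpoints if not stored."""
        if self.t_edges is not None:
            return self.t_edges
        tm = self.t_mid
        if tm.size == 1:  # degenerate: assume unit interval
            return np.array([tm[0] - 0.5, tm[0] + 0.5])
        inner = 0.5 * (tm[1:] + tm[:-1])
        first = tm[0] - (inner[0] - tm[0])
        last = tm[-1] + (tm[-1] - inner[-1])
        return np.concatenate([[first], inner, [last]])


def load_tracks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    pixel_size: float | None = None,
    time_scale: float = 1.0,
) -> list[Trajectory]:
    """Read a CSV track table into per-cell trajectories.

    The canonical dialect has columns ``cell_id, t, x, y`` (optional ``z``);
    ``column_map`` renames arbitrary exporter headers (Imaris, TrackMate) onto
    these, e.g. ``{"TrackID": "cell_id", "Time": "t", ...}``.  If
    ``pixel_size`` is given, x/y (and z) are converted px -> µm; ``time_scale``
    multiplies t into seconds (e.g. 60 for minutes).

    Raises
    ------
    TrackFormatError
        On duplicate (cell, t) rows or non-monotonic time, naming the cell.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["cell_id", "t", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required columns: {missing}")

    trajectories: list[Trajectory] = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t", kind="mergesort")
        t = grp["t"].to_numpy(dtype=float) * time_scale
        if np.any(np.diff(t) == 0):
            raise TrackFormatError(f"duplicate timestamp for cell {cell_id!r}")
        if np.any(np.diff(t) < 0):
            raise TrackFormatError(f"non-monotonic time for cell {cell_id!r}")
        scale = pixel_size if pixel_size is not None else 1.0
        x = grp["x"].to_numpy(dtype=float) * scale
        y = grp["y"].to_numpy(dtype=float) * scale
        z = grp["z"].to_numpy(dtype=float) * scale if "z" in grp.columns else None
        dt = np.diff(t)
        med = np.median(dt)
        if med > 0 and np.any(dt > 2 * med):
            warnings.warn(
                f"cell {cell_id!r}: frame gaps exceed 2x median interval; "
                "no interpolation is applied",
                stacklevel=2,
            )
        trajectories.append(
            Trajectory(cell_id=str(cell_id), t=t, x=x, y=y, z=z, source=str(path))
        )
    log.info("loaded %d trajectories from %s", len(trajectories), path)
    return trajectories


def instantaneous_speed(traj: Trajectory, use_z: bool = False) -> SpeedTrace:
    """Speed between consecutive time points, in µm/h.

    v_i = ||p_{i+1} - p_i|| / (t_{i+1} - t_i); non-uniform frame intervals are
    handled per pair.
    """
    p = traj.positions(use_z=use_z)
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    dt = np.diff(traj.t)
    v = steps / dt * SECONDS_PER_HOUR
    t_mid = 0.5 * (traj.t[1:] + traj.t[:-1])
    return SpeedTrace(cell_id=traj.cell_id, t_mid=t_mid, v=v, t_edges=traj.t.copy())


def net_displacement(traj: Trajectory, use_z: bool = False) -> float:
    """Euclidean distance (µm) between first and last position."""
    p = traj.positions(use_z=use_z)
    return float(np.linalg.norm(p[-1] - p[0]))


def path_length(traj: Trajectory, use_z: bool = False) -> float:
    """Total arc length (µm): sum of consecutive step norms."""
    p = traj.positions(use_z=use_z)
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
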