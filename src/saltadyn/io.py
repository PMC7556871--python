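"""Readers/writers for the pipeline's on-disk formats.

Image stacks are multi-page TIFF with the axis order documented in the
ImageJ-style metadata; tables are CSV; annotations (paths, masks as
polygons, ground truth) and run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phases import MigrationMetrics, PhaseSegmentation
from .ratiometry import ChargeResult
from .tracks import Trajectory

__all__ = [
    "write_stack",
    "read_stack",
    "write_trajectories",
    "write_metrics",
    "write_segmentation",
    "write_charges",
    "write_json",
    "read_path_json",
]


def write_stack(path: str | Path, stack: np.ndarray, axes: str = "TYX") -> None:
    """Write an image stack as multi-page TIFF, recording the axis order."""
    tifffile.imwrite(
        str(path), np.asarray(stack, dtype=np.float32), metadata={"axes": axes}
    )


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_trajectories(path: str | Path, trajectories: list[Trajectory]) -> None:
    frames = []
    for tr in trajectories:
        df = pd.DataFrame({"cell_id": tr.cell_id, "t": tr.t, "x": tr.x, "y": tr.y})
        if tr.z is not None:
            df["z"] = tr.z
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_metrics(path: str | Path, metrics: list[MigrationMetrics]) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": m.cell_id,
                "distance_um": m.distance,
                "percent_migratory": m.percent_migratory,
                "speed_mig_um_h": m.speed_migratory,
                "n_phases_mig": m.n_phases_mig,
            }
            for m in metrics
        ]
    ).to_csv(path, index=False)


def write_segmentation(path: str | Path, segs: list[PhaseSegmentation]) -> None:
    rows = [
        {
            "cell_id": seg.cell_id,
            "state": ph.state.value,
            "t_start": ph.t_start,
            "t_end": ph.t_end,
        }
        for seg in segs
        for ph in seg.phases
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_charges(path: str | Path, charges: list[ChargeResult]) -> None:
    rows = [
        {
            "cell_id": c.cell_id,
            "state": ph.state.value,
            "t_start": ph.t_start,
            "t_end": ph.t_end,
            "charge": ph.charge,
            "baseline": c.baseline,
            "flagged": ph.flagged,
        }
        for c in charges
        for ph in c.phases
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def read_path_json(path: str | Path) -> np.ndarray:
    """Read a polyline annotation: {"path": [[row, col], ...]} in px."""
    data = json.loads(Path(path).read_text())
    return np.asarray(data["path"], dtype=float)
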