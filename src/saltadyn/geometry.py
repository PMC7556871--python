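"""Polyline geometry shared by the renderers, profiles, and kymographs.

Paths are (n, 2) arrays of (row, col) pixel coordinates.  Arc length is
measured along the polyline; pixel-to-path assignment is by nearest point on
a densely resampled version of the path, so the renderer and the profiler
agree exactly on which pixel belongs to which arc-length bin.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["resample_polyline", "tube_pixels", "arc_length"]

DENSE_SPACING = 0.25  # px; dense-resampling step for nearest-point queries


def arc_length(path: np.ndarray) -> np.ndarray:
    """Cumulative arc length (px) at each vertex, starting at 0."""
    path = np.asarray(path, dtype=float)
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def resample_polyline(
    path: np.ndarray, spacing: float = DENSE_SPACING
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length spacing.

    Returns (points, s) where points is (m, 2) and s the arc length (px) of
    each point.  Endpoints are preserved.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
        raise ValueError("path must be an (n>=2, 2) array")
    s = arc_length(path)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate path with zero length")
    n_out = max(int(np.ceil(total / spacing)) + 1, 2)
    s_new = np.linspace(0.0, total, n_out)
    pts = np.column_stack(
        [np.interp(s_new, s, path[:, 0]), np.interp(s_new, s, path[:, 1])]
    )
    return pts, s_new


def tube_pixels(
    shape: tuple[int, int], path: np.ndarray, width: float,
    spacing: float = DENSE_SPACING,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels within width/2 of the path, with their arc-length coordinate.

    Returns (rows, cols, s_px): integer pixel indices inside the tube and the
    arc length (px) of the nearest dense path sample for each pixel.
    """
    pts, s = resample_polyline(path, spacing)
    tree = cKDTree(pts)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = tree.query(coords, k=1)
    inside = dist <= width / 2.0
    return (
        rr.ravel()[inside],
        cc.ravel()[inside],
        s[idx[inside]],
    )
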