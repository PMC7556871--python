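"""Ratiometric biosensor quantification and the per-phase charge statistic.

The ATP/ADP sensor (PercevalHR) is excited at two wavelengths; the per-frame
readout is the ratio of the mean fluorescence intensities of the two channels
within the cell mask (ratio of means, after z max-projection).  The "charge"
of a migration phase is the area under the ratio curve relative to a baseline
-- the mean ratio over all stationary frames of the movie -- divided by the
phase duration, so phases of different lengths are comparable.  Negative
charge means the ratio dipped below its stationary baseline (energy
consumption); the same machinery applies unchanged to the pH sensor (pHRed,
excitation 440/585 nm).

Ratio orientation is configurable; the default channel pair (482, 430) puts
the ATP-sensitive excitation in the numerator so that higher ATP/ADP gives a
higher ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phases import PhaseSegmentation, PhaseState

__all__ = [
    "RatioTrace",
    "PhaseCharge",
    "ChargeResult",
    "compute_ratio_trace",
    "stationary_baseline",
    "phase_charge",
    "percent_normalize",
    "condition_ratio_summary",
]

log = logging.getLogger(__name__)


@dataclass
class RatioTrace:
    """Per-frame biosensor ratio for one cell.

    Invalid frames (denominator below the noise floor) are flagged in
    ``valid`` rather than dropped, so time indexing stays intact.
    """

    cell_id: str
    t: np.ndarray  # s
    r: np.ndarray  # dimensionless ratio
    valid: np.ndarray | None = None
    channel_pair: tuple[float, float] = (482.0, 430.0)  # (num, den) excitation nm
    mask_source: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.r)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.shape == self.r.shape == self.valid.shape):
            raise ValueError("t, r and valid must have equal length")
        if np.any(~np.isfinite(self.r[self.valid])):
            raise ValueError("valid frames must hold finite ratios")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class PhaseCharge:
    state: PhaseState
    t_start: float
    t_end: float
    charge: float | None  # ratio units; None when the phase is too short
    flagged: bool = False


@dataclass
class ChargeResult:
    cell_id: str
    baseline: float
    phases: list[PhaseCharge]

    def charges_of(self, state: PhaseState) -> np.ndarray:
        return np.array(
            [p.charge for p in self.phases if p.state == state and p.charge is not None]
        )


def compute_ratio_trace(
    stack_num: np.ndarray,
    stack_den: np.ndarray,
    mask: np.ndarray,
    t: np.ndarray | None = None,
    cell_id: str = "cell-0",
    channel_pair: tuple[float, float] = (482.0, 430.0),
    den_floor: float | None = None,
    floor_k: float = 3.0,
) -> RatioTrace:
    """Per-frame ratio of channel means within the cell mask.

    Stacks are T(Z)YX; a z max-projection is taken per wavelength when a Z
    axis is present.  The per-frame ratio is mean(num)/mean(den) over the
    mask (ratio of means, not mean of ratios).  Frames whose denominator
    mean falls below the floor are flagged invalid; the default floor is
    background mean + ``floor_k`` x background SD, estimated per frame from
    the mask complement.
    """
    stack_num = np.asarray(stack_num, dtype=float)
    stack_den = np.asarray(stack_den, dtype=float)
    if stack_num.shape != stack_den.shape:
        raise ValueError("numerator and denominator stacks must share a shape")
    if stack_num.ndim == 4:  # T, Z, Y, X -> max-project z per wavelength
        stack_num = stack_num.max(axis=1)
        stack_den = stack_den.max(axis=1)
    if stack_num.ndim != 3:
        raise ValueError("stacks must be TYX or TZYX")
    n_frames = stack_num.shape[0]

    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        masks = np.broadcast_to(mask, stack_num.shape)
    elif mask.shape == stack_num.shape:
        masks = mask
    else:
        raise ValueError("mask must be YX or TYX matching the stacks")
    if not masks.any():
        raise ValueError("mask selects no pixels")

    t = np.arange(n_frames, dtype=float) if t is None else np.asarray(t, dtype=float)
    r = np.full(n_frames, np.nan)
    valid = np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        m = masks[i]
        num_mean = stack_num[i][m].mean()
        den_mean = stack_den[i][m].mean()
        if den_floor is not None:
            floor = den_floor
        else:
            outside = stack_den[i][~m]
            floor = (
                outside.mean() + floor_k * outside.std() if outside.size else 0.0
            )
        if den_mean > floor:
            r[i] = num_mean / den_mean
            valid[i] = True
    if not valid.all():
        log.info(
            "cell %s: %d/%d frames flagged invalid (denominator at floor)",
            cell_id, int((~valid).sum()), n_frames,
        )
    return RatioTrace(
        cell_id=cell_id, t=t, r=r, valid=valid, channel_pair=channel_pair,
        mask_source="mask",
    )


def stationary_baseline(trace: RatioTrace, seg: PhaseSegmentation) -> float:
    """Mean ratio over all valid frames lying in stationary phases."""
    states = seg.state_at(trace.t)
    sel = (states == PhaseState.STAT.value) & trace.valid
    if not np.any(states == PhaseState.STAT.value):
        raise ValueError(
            f"cell {trace.cell_id!r}: no stationary phase; baseline undefined"
        )
    if not sel.any():
        raise ValueError(
            f"cell {trace.cell_id!r}: no valid stationary frames for baseline"
        )
    return float(trace.r[sel].mean())


def phase_charge(
    trace: RatioTrace, seg: PhaseSegmentation, baseline: float
) -> ChargeResult:
    """Per-phase area under (r - baseline) divided by phase duration.

    Trapezoidal integration; values at the phase boundaries are linearly
    interpolated between the bracketing valid frames, which makes the
    integral exact for piecewise-linear traces sampled at their breakpoints
    and makes charges additive: the duration-weighted sum over phases equals
    the total AUC over the movie.  Phases shorter than one frame interval
    (or without enough valid samples) are flagged and their charge omitted.
    """
    tv = trace.t[trace.valid]
    rv = trace.r[trace.valid] - baseline
    if tv.size < 2:
        raise ValueError("need at least two valid frames to integrate")
    frame_dt = float(np.median(np.diff(tv)))

    results: list[PhaseCharge] = []
    for ph in seg.phases:
        dur = ph.t_end - ph.t_start
        inside = (tv > ph.t_start) & (tv < ph.t_end)
        if dur < frame_dt or ph.t_start < tv[0] - frame_dt or ph.t_end > tv[-1] + frame_dt:
            results.append(
                PhaseCharge(ph.state, ph.t_start, ph.t_end, None, flagged=True)
            )
            continue
        t_pts = np.concatenate([[ph.t_start], tv[inside], [ph.t_end]])
        r_pts = np.interp(t_pts, tv, rv)
        auc = float(np.trapezoid(r_pts, t_pts))
        results.append(
            PhaseCharge(ph.state, ph.t_start, ph.t_end, auc / dur, flagged=False)
        )
    return ChargeResult(cell_id=trace.cell_id, baseline=baseline, phases=results)


def percent_normalize(trace: RatioTrace) -> np.ndarray:
    """Trace as a percentage of its per-cell maximum (max frame = 100)."""
    if not trace.valid.any():
        raise ValueError(f"cell {trace.cell_id!r}: no valid frames to normalize")
    peak = trace.r[trace.valid].max()
    if peak <= 0:
        raise ValueError("maximum ratio must be positive for normalization")
    out = np.full_like(trace.r, np.nan)
    out[trace.valid] = 100.0 * trace.r[trace.valid] / peak
    return out


def condition_ratio_summary(
    traces_by_condition: dict[str, list[RatioTrace]]
) -> pd.DataFrame:
    """Mean +/- SEM of the per-cell mean ratio for each condition.

    Empty conditions are omitted with a warning.  Rows keep the insertion
    order of the input mapping (e.g. increasing drug dose).
    """
    rows = []
    for cond, traces in traces_by_condition.items():
        cell_means = [
            float(tr.r[tr.valid].mean()) for tr in traces if tr.valid.any()
        ]
        if not cell_means:
            warnings.warn(f"condition {cond!r} has no cells; omitted", stacklevel=2)
            continue
        arr = np.asarray(cell_means)
        sem = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        rows.append(
            {"condition": cond, "n": arr.size, "mean_ratio": arr.mean(), "sem": sem}
        )
    return pd.DataFrame(rows, columns=["condition", "n", "mean_ratio", "sem"])
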