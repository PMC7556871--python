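"""Synthetic imaging data with exported ground truth.

Every downstream stage of the pipeline (kinematics, phase segmentation,
ratiometry, puncta, profiles) is testable against this module, which emulates
the study system: neuroblasts migrating saltatorily (~110-120 µm/h bursts,
~48% migratory duty cycle), a ratiometric ATP/ADP sensor whose ratio decays
during migratory phases and recovers during pauses, two-channel tandem
reporter puncta fields with a controllable dual-positive fraction, and curved
leading processes with programmed per-bin intensity.

All generators take an explicit integer seed and are bit-reproducible; there
is no global random state.  Defaults are the study's conditions: 30-s frames
for 1 h, migratory speed 116.2 µm/h, duty cycle 0.478, dual-puncta fraction
0.355.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import resample_polyline, tube_pixels
from .tracks import SECONDS_PER_HOUR, Trajectory

__all__ = [
    "GenerationError",
    "GroundTruth",
    "SaltatoryParams",
    "EnergyModelParams",
    "PunctaSceneParams",
    "ProcessImageParams",
    "simulate_trajectory",
    "simulate_energy_trace",
    "render_energy_stacks",
    "render_puncta_stack",
    "render_process_image",
    "render_transport_movie",
    "spawn_seeds",
]


class GenerationError(RuntimeError):
    """Raised when a scene cannot be generated under its constraints."""


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class GroundTruth:
    """Generator-side truth attached to each synthetic output."""

    phase_labels: np.ndarray | None = None  # per-frame 'MIG'/'STAT'
    puncta_list: list[dict] | None = None  # per punctum: y, x, dual
    energy_trace_clean: np.ndarray | None = None  # noiseless ratio series
    profile_means: np.ndarray | None = None  # true per-bin intensities


# --------------------------------------------------------------------------
# Saltatory trajectories
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SaltatoryParams:
    """Two-state (migratory/stationary) saltatory trajectory model.

    Dwell times in each state are exponential (memoryless two-state Markov)
    with a configurable minimum dwell of ``min_dwell_frames`` frames so that
    phases stay resolvable.  ``duty_cycle`` must equal
    mean_phase_mig / (mean_phase_mig + mean_phase_stat).
    """

    frame_interval: float = 30.0  # s
    duration: float = 3600.0  # s
    v_mig: float = 116.2  # µm/h, mean migratory speed
    v_noise: float = 10.0  # µm/h, Gaussian jitter SD (both states)
    duty_cycle: float = 0.478  # long-run migratory fraction
    mean_phase_mig: float = 300.0  # s
    mean_phase_stat: float = 327.615062761506  # s; = 300*(1-0.478)/0.478
    turn_sd: float = 0.17  # rad per frame heading change SD
    min_dwell_frames: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be positive")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must lie in [0, 1]")
        if self.v_mig < 0 or self.v_noise < 0 or self.turn_sd < 0:
            raise ValueError("speeds and turn_sd must be non-negative")
        if self.mean_phase_mig < 0 or self.mean_phase_stat < 0:
            raise ValueError("mean dwell times must be non-negative")
        total = self.mean_phase_mig + self.mean_phase_stat
        if total <= 0:
            raise ValueError("at least one mean dwell time must be positive")
        implied = self.mean_phase_mig / total
        if abs(implied - self.duty_cycle) > 1e-9:
            raise ValueError(
                "duty_cycle inconsistent with mean dwell times: "
                f"{self.duty_cycle} vs {implied}"
            )
        if 0.0 < self.duty_cycle < 1.0 and (
            self.mean_phase_mig <= 0 or self.mean_phase_stat <= 0
        ):
            raise ValueError("interior duty cycle requires positive dwell means")

    @classmethod
    def with_duty_cycle(
        cls, duty_cycle: float, mean_phase_mig: float = 300.0, **kwargs
    ) -> "SaltatoryParams":
        """Construct with mean_phase_stat derived from the duty cycle."""
        if duty_cycle <= 0.0:
            return cls(duty_cycle=0.0, mean_phase_mig=0.0,
                       mean_phase_stat=mean_phase_mig, **kwargs)
        if duty_cycle >= 1.0:
            return cls(duty_cycle=1.0, mean_phase_mig=mean_phase_mig,
                       mean_phase_stat=0.0, **kwargs)
        stat = mean_phase_mig * (1.0 - duty_cycle) / duty_cycle
        return cls(duty_cycle=duty_cycle, mean_phase_mig=mean_phase_mig,
                   mean_phase_stat=stat, **kwargs)


def _dwell_states(params: SaltatoryParams, n_intervals: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-interval boolean migratory states from exponential dwells."""
    if params.duty_cycle <= 0.0:
        return np.zeros(n_intervals, dtype=bool)
    if params.duty_cycle >= 1.0:
        return np.ones(n_intervals, dtype=bool)
    states = np.empty(n_intervals, dtype=bool)
    state = bool(rng.random() < params.duty_cycle)
    i = 0
    while i < n_intervals:
        mean = params.mean_phase_mig if state else params.mean_phase_stat
        dwell_s = rng.exponential(mean)
        dwell = max(
            int(round(dwell_s / params.frame_interval)), params.min_dwell_frames
        )
        states[i : i + dwell] = state
        i += dwell
        state = not state
    return states


def simulate_trajectory(
    params: SaltatoryParams, cell_id: str = "synth-0"
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one saltatory trajectory with per-frame phase labels.

    Per frame interval the displacement is (state speed x dt) along a heading
    with Gaussian persistence (SD ``turn_sd``/frame) plus isotropic Gaussian
    positional jitter of SD ``v_noise * dt`` per component.
    """
    rng = np.random.default_rng(params.seed)
    n_int = int(round(params.duration / params.frame_interval))
    if n_int < 1:
        raise ValueError("duration must cover at least one frame interval")
    dt_h = params.frame_interval / SECONDS_PER_HOUR
    states = _dwell_states(params, n_int, rng)

    theta = rng.uniform(0.0, 2.0 * math.pi)
    pos = np.zeros((n_int + 1, 2))
    for i in range(n_int):
        theta += rng.normal(0.0, params.turn_sd)
        v = params.v_mig if states[i] else 0.0
        step = v * dt_h * np.array([math.cos(theta), math.sin(theta)])
        step = step + rng.normal(0.0, params.v_noise * dt_h, size=2)
        pos[i + 1] = pos[i] + step

    t = np.arange(n_int + 1) * params.frame_interval
    traj = Trajectory(
        cell_id=cell_id, t=t, x=pos[:, 0], y=pos[:, 1], source="synthio"
    )
    labels = np.where(states, "MIG", "STAT").astype(object)
    frame_labels = np.concatenate([labels, [labels[-1]]])
    return traj, GroundTruth(phase_labels=frame_labels)


# --------------------------------------------------------------------------
# Energy (ATP/ADP sensor) traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyModelParams:
    """Piecewise-linear ratio dynamics coupled to the migration state.

    The ratio sits at ``r0`` at rest, falls at ``drop_rate`` per second while
    migrating and recovers at ``recovery_rate`` per second while stationary,
    clipped to [r_floor, r0].  The sensor is emitted as two excitation
    channels whose mean-intensity ratio equals the clean model ratio before
    noise; ``noise_sd`` (ratio units) scales independent Gaussian noise added
    to each channel.
    """

    r0: float = 1.5
    drop_rate: float = 4.0e-4  # ratio units / s, migratory
    recovery_rate: float = 1.6e-3  # ratio units / s, stationary
    r_floor: float = 1.0
    noise_sd: float = 0.01
    den_level: float = 1000.0  # denominator-channel mean intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_floor >= self.r0:
            raise ValueError("r_floor must be below r0")
        if self.drop_rate < 0 or self.recovery_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise_sd must be non-negative")
        if self.den_level <= 0:
            raise ValueError("den_level must be positive")


def simulate_energy_trace(
    phase_labels: np.ndarray, frame_interval: float, params: EnergyModelParams
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Dual-channel sensor trace for a per-frame phase-label sequence.

    Returns (num, den): per-frame mean intensities of the numerator and
    denominator excitation channels, with num/den equal to the clean ratio
    before noise.  The clean ratio drops during migratory frames and recovers
    (with clipping at r0) during stationary frames.
    """
    labels = np.asarray(phase_labels, dtype=object)
    if labels.size == 0:
        raise ValueError("phase sequence must be non-empty")
    rng = np.random.default_rng(params.seed)
    n = labels.size
    r = np.empty(n)
    r[0] = params.r0
    for i in range(1, n):
        if str(labels[i - 1]) == "MIG":
            r[i] = r[i - 1] - params.drop_rate * frame_interval
        else:
            r[i] = r[i - 1] + params.recovery_rate * frame_interval
        r[i] = min(max(r[i], params.r_floor), params.r0)

    den = np.full(n, params.den_level)
    num = r * params.den_level
    if params.noise_sd > 0:
        scale = params.noise_sd * params.den_level
        num = num + rng.normal(0.0, scale, n)
        den = den + rng.normal(0.0, scale, n)
    return num, den, GroundTruth(energy_trace_clean=r)


def render_energy_stacks(
    num: np.ndarray,
    den: np.ndarray,
    shape: tuple[int, int] = (16, 16),
    cell_radius: float = 5.0,
    background: float = 0.0,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render per-frame channel means as uniform-cell image stacks.

    Returns (stack_num, stack_den, mask), stacks of shape (T, H, W) with the
    cell disk filled at the per-frame channel value so that the masked mean
    reproduces the input trace exactly at zero pixel noise.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    rng = np.random.default_rng(seed)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    mask = (rr - h / 2.0) ** 2 + (cc - w / 2.0) ** 2 <= cell_radius**2
    stacks = []
    for trace in (num, den):
        stack = np.full((trace.size, h, w), background, dtype=float)
        stack[:, mask] = trace[:, None]
        if pixel_noise_sd > 0:
            stack += rng.normal(0.0, pixel_noise_sd, stack.shape)
        stacks.append(stack)
    return stacks[0], stacks[1], mask


# --------------------------------------------------------------------------
# Puncta scenes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PunctaSceneParams:
    """Two-channel Gaussian-spot scene for tandem-reporter flux analysis.

    Every punctum appears in the detection (RFP) channel; a Bernoulli
    ``frac_dual`` subset also appears in the secondary (GFP) channel.  Peak
    amplitude is ``peak_snr * noise_sd``; positions are uniform with a
    minimum separation of ``min_sep_factor * psf_sigma`` enforced by bounded
    rejection sampling.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.2  # µm/px
    n_puncta: int = 60
    frac_dual: float = 0.355
    psf_sigma: float = 1.5  # px
    peak_snr: float = 5.0
    background: float = 100.0
    noise_sd: float = 10.0
    min_sep_factor: float = 4.0
    amp_jitter: float = 0.1  # relative amplitude variation
    poisson_noise: bool = False
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_dual <= 1.0:
            raise ValueError("frac_dual must lie in [0, 1]")
        if self.peak_snr <= 0:
            raise ValueError("peak_snr must be positive")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be non-negative")


def _sample_positions(params: PunctaSceneParams,
                      rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_shape
    margin = 3.0 * params.psf_sigma
    min_sep = params.min_sep_factor * params.psf_sigma
    pts: list[np.ndarray] = []
    for _ in range(params.n_puncta):
        for attempt in range(params.max_retries):
            cand = np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            )
            if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
                pts.append(cand)
                break
        else:
            raise GenerationError(
                f"could not place {params.n_puncta} puncta with min separation "
                f"{min_sep:.1f} px in {params.image_shape} after "
                f"{params.max_retries} retries"
            )
    return np.array(pts) if pts else np.empty((0, 2))


def _add_spot(img: np.ndarray, y: float, x: float, amp: float,
              sigma: float) -> None:
    h, w = img.shape
    r = int(math.ceil(4.0 * sigma))
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    rr, cc = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((rr - y) ** 2 + (cc - x) ** 2) / (2.0 * sigma**2)
    )


def render_puncta_stack(
    params: PunctaSceneParams,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one two-channel scene; returns ((2, H, W) stack, truth).

    Channel 0 is the detection (RFP) channel, channel 1 the secondary (GFP)
    channel containing only the dual-labeled puncta.
    """
    rng = np.random.default_rng(params.seed)
    positions = _sample_positions(params, rng)
    dual = rng.random(positions.shape[0]) < params.frac_dual
    amp = params.peak_snr * params.noise_sd

    h, w = params.image_shape
    rfp = np.full((h, w), params.background, dtype=float)
    gfp = np.full((h, w), params.background, dtype=float)
    truth: list[dict] = []
    for (y, x), is_dual in zip(positions, dual):
        a_r = amp * (1.0 + params.amp_jitter * rng.uniform(-1.0, 1.0))
        _add_spot(rfp, y, x, a_r, params.psf_sigma)
        if is_dual:
            a_g = amp * (1.0 + params.amp_jitter * rng.uniform(-1.0, 1.0))
            _add_spot(gfp, y, x, a_g, params.psf_sigma)
        truth.append({"y": float(y), "x": float(x), "dual": bool(is_dual)})

    if params.poisson_noise:
        rfp = rng.poisson(np.clip(rfp, 0, None)).astype(float)
        gfp = rng.poisson(np.clip(gfp, 0, None)).astype(float)
    if params.noise_sd > 0:
        rfp += rng.normal(0.0, params.noise_sd, rfp.shape)
        gfp += rng.normal(0.0, params.noise_sd, gfp.shape)
    return np.stack([rfp, gfp]), GroundTruth(puncta_list=truth)


# --------------------------------------------------------------------------
# Leading-process images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProcessImageParams:
    """Curved-tube render of a leading process with per-bin intensities."""

    image_shape: tuple[int, int] = (128, 192)
    pixel_size: float = 1.0  # µm/px
    bin_width: float = 20.0  # µm
    tube_width: float = 10.0  # px, rendered full width
    soma_radius: float = 8.0  # px
    background: float = 0.0
    noise_sd: float = 0.0
    curve_amp: float = 6.0  # px, sinusoidal path perturbation
    seed: int = 0


def _process_path(params: ProcessImageParams, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Soma center and a curved polyline of n_bins*bin_width arc length."""
    h, w = params.image_shape
    soma = np.array([h / 2.0, 2.0 + params.soma_radius])
    length_px = n_bins * params.bin_width / params.pixel_size
    # build an over-long sine path, then trim to the requested arc length
    n_samp = int(length_px * 3) + 10
    cols = soma[1] + params.soma_radius + np.linspace(0.0, 1.3 * length_px, n_samp)
    u = np.linspace(0.0, 1.0, n_samp)
    rows = soma[0] + params.curve_amp * np.sin(2.0 * math.pi * u)
    path = np.column_stack([rows, cols])
    pts, s = resample_polyline(path, spacing=0.25)
    keep = s < length_px
    # end the path at exactly the requested arc length
    end = np.array(
        [np.interp(length_px, s, pts[:, 0]), np.interp(length_px, s, pts[:, 1])]
    )
    pts = np.vstack([pts[keep], end])
    if pts[:, 1].max() >= w - 1 or pts[:, 0].max() >= h - 1 or pts[:, 0].min() <= 0:
        raise GenerationError("process path does not fit the image; enlarge it")
    return soma, pts


def render_process_image(
    bin_means: np.ndarray,
    soma_mean: float,
    params: ProcessImageParams = ProcessImageParams(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render a soma disk plus a curved process tube with per-bin intensity.

    Returns (image, path, soma_mask, truth).  Tube pixels take
    background + bin_means[bin of their arc-length]; the soma disk takes
    background + soma_mean and overrides the tube where they touch.
    """
    bin_means = np.asarray(bin_means, dtype=float)
    if bin_means.size < 1:
        raise ValueError("at least one bin mean is required")
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    soma, path = _process_path(params, bin_means.size)

    img = np.full((h, w), params.background, dtype=float)
    rows, cols, s_px = tube_pixels((h, w), path, params.tube_width)
    s_um = s_px * params.pixel_size
    bins = np.minimum(
        (s_um / params.bin_width).astype(int), bin_means.size - 1
    )
    img[rows, cols] = params.background + bin_means[bins]

    rr, cc = np.mgrid[0:h, 0:w]
    soma_mask = (rr - soma[0]) ** 2 + (cc - soma[1]) ** 2 <= params.soma_radius**2
    img[soma_mask] = params.background + soma_mean
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    return img, path, soma_mask, GroundTruth(profile_means=bin_means.copy())


# --------------------------------------------------------------------------
# Puncta transport movies (kymograph inputs)
# --------------------------------------------------------------------------


def render_transport_movie(
    path: np.ndarray,
    n_frames: int,
    start_s: np.ndarray,
    speed_s: np.ndarray,
    psf_sigma: float = 1.5,
    amplitude: float = 100.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    image_shape: tuple[int, int] = (64, 128),
    seed: int = 0,
) -> np.ndarray:
    """Movie of puncta moving along a polyline at constant signed speeds.

    ``start_s`` and ``speed_s`` are per-punctum arc positions (px) and speeds
    (px/frame); positions are clipped to the path ends.  Returns (T, H, W).
    """
    rng = np.random.default_rng(seed)
    pts, s = resample_polyline(path, spacing=0.25)
    total = s[-1]
    start_s = np.atleast_1d(np.asarray(start_s, dtype=float))
    speed_s = np.atleast_1d(np.asarray(speed_s, dtype=float))
    stack = np.full((n_frames, *image_shape), background, dtype=float)
    for f in range(n_frames):
        frame = stack[f]
        pos = np.clip(start_s + speed_s * f, 0.0, total)
        for p in pos:
            y = np.interp(p, s, pts[:, 0])
            x = np.interp(p, s, pts[:, 1])
            _add_spot(frame, y, x, amplitude, psf_sigma)
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)
    return stack
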