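# Methods

This note documents the models and estimators implemented in `saltadyn`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that affect results.

## Saltatory trajectory model (`synthio`)

Cell state alternates between *migratory* (MIG) and *stationary* (STAT) as a
two-state Markov process: dwell times are exponential with means
`mean_phase_mig` and `mean_phase_stat`, subject to a minimum dwell of
`min_dwell_frames = 2` frames so that no phase falls below the temporal
resolution of the movie. The long-run migratory fraction (duty cycle) is
`mean_phase_mig / (mean_phase_mig + mean_phase_stat)` and is validated to
1e-9 against the `duty_cycle` field. The 2-frame floor perturbs the duty
cycle by < 0.1 percentage points at the default dwell scales.

Per frame interval the displacement is `v_state · Δt` along a heading that
performs a Gaussian random walk (`turn_sd` per frame), plus isotropic
Gaussian positional jitter with SD `v_noise · Δt` per component, applied in
both states. Defaults are the conditions the analysis is built for:

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `frame_interval` | 30 | s | acquisition cadence of the sensor movies |
| `duration` | 3600 | s | 1-h movies |
| `v_mig` | 116.2 | µm/h | printed wild-type migratory-phase speed |
| `duty_cycle` | 0.478 | — | printed wild-type percent migratory |
| `mean_phase_mig` | 300 | s | minutes-scale bursts; sets ~5–6 cycles/h |
| `v_noise` | 10 | µm/h | tracking jitter, ~10% of the migratory speed |
| `turn_sd` | 0.17 | rad/frame | calibrated so the ensemble 1-h net displacement matches the printed 43.4 µm given speed and duty cycle |

`turn_sd` and `mean_phase_mig` are the two quantities the source data do not
print directly; `turn_sd` was calibrated once against the printed net
migration distance (a printed value, not a test threshold), and the dwell
scale was fixed at the minutes scale apparent in the published example
traces.

## Energy (ATP/ADP sensor) model

The published data show the ratio falling after migratory onset and
recovering to a plateau during pauses, but give no kinetic constants. The
model is deliberately the simplest process with that phenomenology:
piecewise-linear dynamics clipped to `[r_floor, r0]` —

    dr/dt = −drop_rate      (MIG)
    dr/dt = +recovery_rate  (STAT),  r ∈ [r_floor, r0]

with defaults `r0 = 1.5`, `r_floor = 1.0`, `drop_rate = 4e-4 /s`,
`recovery_rate = 1.6e-3 /s`, `noise_sd = 0.01` (ratio units, per channel).
Linearity makes phase charges analytically checkable (trapezoid integration
is exact). Recovery is faster than the drop so that a typical stationary
dwell completes recovery and plateaus at `r0`, as in the published example
traces; this asymmetry is what gives the stationary baseline its meaning.
With symmetric rates the trace is a near-symmetric sawtooth, the baseline
sits mid-ramp, and both phase charges shrink toward zero — the migratory
vs. stationary contrast then has only ~64% power at n = 19 across seeds,
i.e. the generator would fail to emulate an effect the source study detected
at that n. The defaults were frozen after a 25-seed power check (all 25
significant, max p = 0.010); they were not adjusted per seed.

The sensor is emitted as two excitation channels whose mean-intensity ratio
equals the clean model ratio; Gaussian noise is added independently per
channel, so the measured ratio of noisy means is biased only at second order
in `noise_sd`.

## Phase segmentation

The source analysis called phases manually from the instantaneous-speed
profile. The explicit rule here:

1. optional centered moving average (window `w` frames);
2. hysteresis classification: enter MIG at `v ≥ v_on = 40 µm/h`, exit at
   `v < v_off = 20 µm/h` (thresholds sit in the anti-mode between ~0 and
   ~110–120 µm/h speed clusters; the band prevents threshold chatter);
3. boundary refinement: each coarse boundary moves to the position within
   ±`w` frames that best separates raw speeds about the threshold midpoint
   `(v_on+v_off)/2` (ties: nearest to the coarse boundary, then earlier);
4. phases shorter than `min_dwell = 2` frames are merged into the neighbor
   sharing the longer boundary phase (earlier neighbor on ties).

**Smoothing default is `w = 1` (off).** A moving average of width w cannot
represent genuine phases shorter than w frames: at exponential dwell times a
fifth of stationary pauses last ~2 frames, and at w = 3 such a pause smooths
to ≈ 39 µm/h — above `v_off` — and is silently absorbed into the flanking
migratory phase. Measured on 100 simulated cells, w = 3 inflates percent
migratory by ~3 points, depresses migratory speed by ~7 µm/h and caps
boundary F1 at ~0.87, whereas w = 1 recovers 99.7% frame accuracy and
F1 ≈ 0.99. Hysteresis alone provides the chatter immunity smoothing was
meant to buy. The window remains configurable for noisier data, and every
output records the full threshold configuration, since all phase-dependent
quantities are conditional on it.

Metrics use the full movie duration as the denominator for percent
migratory; migratory speed averages raw instantaneous speeds over frames
whose midpoints fall in migratory phases and is flagged undefined for cells
with none. Fully stationary cells are excluded from ensembles (the source
study's rule), with the count logged.

## Charge

`charge = ∫(r − baseline) dt / duration` per phase, with the baseline the
mean ratio over all valid stationary frames of the whole movie. Numerics:
trapezoidal integration with phase-boundary values linearly interpolated
between bracketing frames — exact for piecewise-linear traces sampled at
their breakpoints, and additive: the duration-weighted sum of phase charges
equals the total AUC to 1e-9. Phases shorter than one frame interval are
flagged and their charge omitted. Charge is invariant to the time unit and
to adding a constant to the trace.

Ratio orientation: numerator 482 nm excitation, denominator 430 nm, so a
higher ATP/ADP ratio gives a larger r (the convention for this sensor
family); the orientation is configurable, as the source does not state it.
The pH sensor (channel pair 585/440 nm) uses identical machinery. Frames
whose denominator mean falls below `background mean + 3·SD` (estimated from
the mask complement) are flagged invalid rather than dropped. No
photobleaching correction is applied by default.

## Puncta

Detection runs only on the RFP channel (the tandem reporter marks every
vesicle there); secondary channels add labels. The detector is
scale-normalized LoG filtering at `psf_sigma = 1.5 px` with threshold
`k · SD` where SD is the robust (MAD) noise level of the response image.
**Detection `k = 5`:** at k = 3 the expected number of spurious local maxima
over a 128×128 response field is ~5 per frame (precision 0.89 at 60 true
spots), which biases count-based statistics — the normalized density
contrast read ~73% instead of the programmed 66%. k = 5 yields precision
1.00 / recall 0.998 at peak SNR 5 and leaves the density contrast unbiased.

Classification: a punctum is positive in a secondary channel when the mean
over a radius-`ρ = 2 px` disk exceeds the local background (median of a
4–7 px annulus) by `k = 3` standard errors of the disk mean (pixel noise
estimated by MAD over the channel). Measured against per-scene ground
truth the estimator is unbiased to < 0.1 percentage points.

Densities are sampled at the first, middle (floor of the index midpoint)
and last frame of each phase, averaged, and normalized to the first
stationary phase (100 by construction); phases with < 3 frames use what
they have and are flagged. Kymographs sample bilinear intensity at 1-px arc
steps with a max over a 3-px perpendicular width.

Ground-truth matching (evaluation only) is greedy nearest-neighbor within
2 px, ties by distance then truth id.

## Profiles

Preprocessing follows the published order: rolling-ball background
subtraction (morphological opening with a 50-px ball) then a 2-px-radius
median filter. Bins are measured in arc length along the traced path (not
Euclidean distance — processes curve), with pixels assigned to their
nearest point on a densely resampled (0.25 px) version of the path within a
tube of width 6 px (the process caliber at the relevant magnifications; the
source does not state the averaging width). The renderer and the profiler
share the same assignment rule, so noiseless recovery is exact. The last
bin is reported with its actual length and flagged when partial.

On noisy images, morphological background estimation tracks the noise
*lower envelope*, which offsets the subtracted image upward by a constant
that is identical under the tube and in empty regions. Profile recovery is
therefore assessed net of the far-field background estimate (mean over
pixels > 2 tube-widths from the path), which cancels the offset; the
residual geometric bias of a 50-px ball under a 10-px-wide ridge is
< 0.3 intensity units.

## Statistics

Formulas are authored directly on scipy distribution functions (scipy's own
test functions serve as independent cross-checks in the test suite, never
as the implementation):

- unpaired two-sided t-test, preceded by a two-sided variance-ratio F-test;
  pooled Student's t when the F-test accepts at α = 0.05, Welch's t
  otherwise. The source verified variance equality but does not say what it
  did on failure; the fallback policy is explicit, recorded in every result,
  and can be forced either way.
- one-way ANOVA with Fisher's LSD post hoc:
  `t_ij = (m_i − m_j)/√(MSE(1/n_i + 1/n_j))`, df = N − k, **unadjusted**
  two-sided p-values (that is what Fisher's LSD is). With k = 2 this reduces
  exactly to the pooled t-test and F = t².
- Reports are mean ± SEM per group with stars at p < 0.05 / 0.01 / 0.001.
  The unit of replication is the cell; animal-level nesting is reported
  descriptively, not modeled.

Degenerate inputs (both groups constant) are flagged rather than producing
NaN p-values.

## What the generator does and does not emulate

Emulated: two-state saltatory kinematics at the printed speed/duty,
phase-coupled sensor dynamics, two-channel Gaussian-spot puncta fields with
controllable dual fraction and minimum separation (4·σ, so ground truth is
unambiguous), state-dependent puncta counts, curved-process intensity
gradients, Gaussian read noise (Poisson noise available, off by default).

Not emulated: photorealistic optics (z-dependent PSF, bleaching, stage
drift), cell-shape changes, segmentation/tracking errors upstream of the
track tables, puncta motion within a frame, or animal-level clustering.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every real-world artifact.

## Problem sizes

The bundled studies use 200 cells for migration metrics, 19 for charge, 18
for phase-resolved flux, 11 for densities and 20 scenes for detection —
the per-figure cohort sizes of the source experiments, which also keep the
full reproduction script under a minute on one CPU.

## Known limitations

- The phase-calling thresholds are explicit stand-ins for a manual
  judgment; all phase-dependent results carry their configuration.
- The linear energy model is a stand-in for unknown kinetics; only signs
  and orderings of charges are meaningful, not magnitudes.
- Manual puncta-counting criteria are unknowable; LoG defaults are
  validated on synthetic truth only.
- 2D kinematics by default (the source analyzed maximum-intensity
  projections); a 3D switch exists for track tables with z.
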