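# saltadyn

Quantitative analysis of **saltatory neuroblast migration** from time-lapse
microscopy: phase segmentation, migration metrics, ratiometric ATP/ADP
"charge" quantification, tandem-reporter autophagic-flux measurement,
leading-process intensity profiling, and the accompanying statistics — plus a
synthetic-data generator that makes every stage testable against ground
truth.

## The scientific problem

Neuroblasts migrating along the rostral migratory stream move *saltatorily*:
bursts of movement at ~110–120 µm/h alternate with stationary pauses.
Energy state (the ATP/ADP ratio, reported by the dual-excitation sensor
PercevalHR) and autophagy (reported by the tandem RFP-GFP-LC3 probe, whose
GFP is quenched in acidic autolysosomes) are both modulated by this cycle.
Quantifying that coupling requires a reproducible chain from raw movies to
per-cell statistics:

- **Kinematics** — instantaneous speed `v_i = ‖p_{i+1} − p_i‖ / Δt` (µm/h),
  net displacement `‖p_last − p_first‖`, path length.
- **Phase segmentation** — hysteresis thresholding of the speed trace
  (enter migratory at `v ≥ v_on = 40 µm/h`, exit at `v < v_off = 20 µm/h`)
  with boundary refinement and minimum-dwell merging. Metrics: percent
  migratory (Σ migratory durations / movie duration), migratory-phase speed,
  net migration distance. Cells that never migrate are excluded.
- **Charge** — for each phase, the area under the ratio-vs-time curve
  relative to a baseline, divided by the phase duration:
  `charge = ∫(r(t) − r̄_stat) dt / (t_end − t_start)`, with the baseline
  `r̄_stat` the mean ratio over all stationary frames of the movie. Negative
  charge during migratory phases means net energy consumption.
- **Autophagic flux** — puncta detected by Laplacian-of-Gaussian filtering
  on the RFP channel; autophagosome fraction = `100 · |GFP⁺∩RFP⁺| / |RFP⁺|`;
  per-phase puncta densities sampled at the beginning/middle/end of each
  phase and normalized to the first stationary phase (= 100%); kymographs
  along the leading process.
- **Profiles** — rolling-ball (50 px) + median (2 px) preprocessing, then
  soma mean and 20-µm arc-length bins along the leading process (first bin
  proximal, last distal).
- **Statistics** — unpaired two-sided Student's t-test with an F-test
  variance check (Welch fallback), one-way ANOVA + Fisher LSD post hoc,
  mean ± SEM reports with `*p<0.05, **p<0.01, ***p<0.001`.

## Worked example

Run the bundled demo scenario — 15 simulated sensor-expressing neuroblasts,
phase segmentation, migration metrics, and per-phase charges:

```sh
saltadyn run configs/demo.yaml --out demo-out
```

```json
{
  "boundary_f1": 0.9921385281385281,
  "charge_mig_mean": -0.03165662053588875,
  "charge_stat_mean": -0.005761252062380213,
  "charge_ttest": "t_unpaired",
  "charge_ttest_p": 0.0007560621196945942,
  "distance_mean_um": 39.18197376370928,
  "n_cells": 15,
  "n_excluded_fully_stationary": 0,
  "percent_migratory_mean": 46.166666666666664,
  "segmentation_accuracy": 0.9977777777777779,
  "speed_migratory_mean": 116.75116577914754
}
```

Reading this: the cohort migrated ~46% of the hour at ~117 µm/h during
migratory phases, covering ~39 µm net. Segmentation agrees with the
generator's ground-truth phase labels on 99.8% of frames. The mean charge is
clearly negative in migratory phases (−0.032) and near zero in stationary
phases (−0.006); the unpaired t-test (pooled, since the F-test accepted
variance equality) finds the contrast at p ≈ 8 × 10⁻⁴ — the ATP/ADP ratio
dips while cells move and recovers while they pause. Result files
(`tracks.csv`, `metrics.csv`, `phases.csv`, `charges.csv`, `summary.csv`)
and a provenance manifest land in `demo-out/`.

The same operations are importable directly:

```python
from saltadyn import (SaltatoryParams, simulate_trajectory,
                      instantaneous_speed, segment_phases, migration_metrics)

traj, truth = simulate_trajectory(SaltatoryParams(seed=1))
trace = instantaneous_speed(traj)
seg = segment_phases(trace)
print(migration_metrics(traj, seg, trace))
```

## Layout

| Module | Role |
| --- | --- |
| `saltadyn.synthio` | synthetic trajectories, sensor traces, puncta scenes, process images (+ ground truth) |
| `saltadyn.tracks` | track-table ingestion, speed/displacement kinematics |
| `saltadyn.phases` | phase segmentation, migration metrics, exclusion rules |
| `saltadyn.ratiometry` | ratio traces, stationary baseline, per-phase charge |
| `saltadyn.puncta` | LoG detection, secondary-channel classification, flux, densities, kymographs |
| `saltadyn.profiles` | preprocessing and 20-µm-bin intensity profiles |
| `saltadyn.statsrep` | t/F tests, ANOVA + Fisher LSD, mean ± SEM reports |
| `saltadyn.config` / `runner` / `io` / `cli` | YAML scenarios, end-to-end runner, formats, `saltadyn` CLI |

See `docs/methods.md` for the models, parameter choices, and limitations.
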