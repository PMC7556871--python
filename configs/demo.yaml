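# Demo scenario: simulate a small cohort of saltatory neuroblasts,
# segment phases, compute migration metrics and per-phase ATP/ADP charges.
name: demo
seed: 7
n_cells: 15
stages: [simulate, phases, ratiometry, stats]
saltatory:
  frame_interval: 30.0     # s
  duration: 3600.0         # s (1 h movie)
  v_mig: 116.2             # µm/h
  duty_cycle: 0.478
  mean_phase_mig: 300.0    # s
  mean_phase_stat: 327.615062761506
energy:
  r0: 1.5
  drop_rate: 0.0004        # ratio units / s while migrating
  recovery_rate: 0.0016    # ratio units / s while stationary
  noise_sd: 0.01
segmentation:
  v_on: 40.0               # µm/h
  v_off: 20.0
  min_dwell: 2
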