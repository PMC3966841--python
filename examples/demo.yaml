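seed: 5
output_dir: scratch/demo_out
log_level: INFO
stages:
  - simulate_oct:
      n_eyes: 3
      n_bscans: 4
      n_lrps_per_bscan: 200
      onl_thickness_mean: 66.4
      onl_thickness_sd: 7.6
      total_thickness_mean: 197.4
      total_thickness_sd: 13.0
      rpe_curvature_amplitude: 10.0
      noise_sd: 0.04
      rosette_count_by_sector:
        superior: 3
        inferior: 5
  - segment: {}
  - enface:
      scheme: halves
      threshold_mode: robust
  - simulate_erg:
      intercept_log: 2.6203
      slope_log: -0.015396
      scatter_sd: 0.2
      ages: [31, 39, 47, 55, 63, 71, 79, 83]
      n_per_age: 6
  - fit_decay:
      stimulus: UV
  - plan_window:
      inject_age: 37
      assess_delay: 28
      asym_log: 0.3
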