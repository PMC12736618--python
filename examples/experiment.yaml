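# Example experiment: 12 h desk-scale study with explicit plant targets.
# All scalar fields are SI units and mirror the library dataclasses.
circuit:
  r_series: 10.0e+3     # ohm
  l_tank: 30.0e-3       # henry
  c_tank: 1.0e-9        # farad
  r_damp: 4.7e+3        # ohm
  c_couple: 10.0e-9     # farad
  r_env: 1.0e+6         # ohm
  c_env: 100.0e-12      # farad

sweep:
  f_start: 20.0e+3      # Hz
  f_stop: 249.0e+3      # Hz  (inclusive grid -> 230 points)
  f_step: 1.0e+3        # Hz
  dwell: 1.0e-3         # s

profile:
  dark_target:  {r0: 50.0e+3, r_inf: 2.0e+3, tau: 2.0e-6, alpha: 0.8}
  light_target: {r0: 35.0e+3, r_inf: 2.0e+3, tau: 1.6e-6, alpha: 0.8}
  tau_resp: 5.0         # minutes
  drift_sd: 0.002       # per sqrt(minute), shared on r0/r_inf
  noise_sd: 0.04        # amplitude units (2% of full scale 2.0)
  profile_id: plant-A

split: {train_frac: 0.6, val_frac: 0.2, test_frac: 0.2}

experiment:
  duration_min: 720
  min_phase: 60
  max_phase: 180
  sweeps_per_burst: 20
  filter_window: 10
  cross_plant: true
  variant_shift: 0.3
  variant_seed: 11
  seed: 7
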