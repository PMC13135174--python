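# Full pipeline configuration (every key optional; values shown are defaults).
seed: 0

preprocess:
  target_fs: 2000
  wavelet: sym3
  levels: 3
  threshold_mode: soft

ewt:
  boundaries_hz: [150, 500]   # sensitivity variants: [120, 450] or [180, 550]
  tau_over_pi: 0.1
  nfft: 1024

cohort:
  groups:                     # [low %, high %, participants]
    - [0, 0, 10]
    - [30, 30, 10]
    - [40, 50, 10]
    - [50, 60, 15]
    - [70, 75, 10]
    - [85, 85, 10]
    - [90, 95, 10]
  n_cycles: 14
  n_keep: 10

sim:
  noise_snr_db: 50
  murmur_gain_scale: 0.04     # calibrated: mean e2 ~ 1e-6 V^2*s at 30 % stenosis
  murmur_gain_power: 1.5
  cycle_gain_jitter_sd: 0.2

segmentation:
  use_r_times: true

classify:
  train_n: 60
  test_n: 15
  test_counts: {mild: 5, moderate: 4, severe: 6}
  cv_splits: 5
  fast_grids: false
  models: [svm, gbm]
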