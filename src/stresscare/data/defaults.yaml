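# Frozen pipeline defaults. Every tunable that the method leaves open is
# pinned here so experiments are reproducible and the resolved values are
# greppable. Command-line flags and user configs override these.
preprocess:
  hr_low_bpm: 38.0          # lower heart-rate bound (rest)
  hr_high_bpm: 220.0        # upper heart-rate bound (exercise/tachycardia)
  butter_order: 3           # Butterworth band-pass order (applied zero-phase)
  smooth_poly_order: 3      # Savitzky-Golay polynomial order
  smooth_window_samples: 10 # Savitzky-Golay window (rounded up to odd 11)
  window_s: 50.0            # sliding-window length W
  stride_s: 8.0             # sliding-window stride S

experiment:
  device: wrist
  task: two_class            # two_class | three_class
  branches: [WB1, WB2, WB3]  # ids from the shipped branch registry
  branch_backend: gradient_boosting
  gate_backend: null         # null -> per-device default below
  gate_backend_by_device:    # motion gate on the wrist, muscle gate on the chest
    wrist: random_forest
    chest: gradient_boosting
  b: 0.5                     # branch-selection threshold in [0, 1]
  fusion: average            # average | majority
  protocol: loso             # loso | kfold
  n_folds: 5                 # used only for kfold
  seed: 0

synth:
  n_subjects: 8
  label_rate_hz: 4.0
  devices: [wrist]
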