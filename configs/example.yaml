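# Two-group developmental contrast at desk scale.
# Run with:  munet run-all --config configs/example.yaml --out runs/demo
seed: 1
n_channels: 12
spacing: 13.0          # mm, nearest-neighbor sensor pitch
fs: 500.0              # Hz
duration: 64.0         # s per subject
n_events: 3            # prehension onsets per subject
noise_sd: 0.3
groups:
  - name: mature
    n_subjects: 6
    impf: 9.0          # Hz, individual mu peak frequency
    age: 25.0
    suppression: 0.7   # mu amplitude factor during prehension
    coupling: {kind: modular, n_modules: 2, module_size: 4, within: 0.75}
  - name: immature
    n_subjects: 6
    impf: 7.0
    age: 0.5
    suppression: 0.7
    coupling: {kind: uniform, strength: 0.12}
analysis:
  wide_low: 0.5        # Hz
  wide_high: 40.0      # Hz
  filter_order: 3      # forward-reverse Butterworth
  band_offset: 2.0     # mu band = impf +/- 2 Hz
  epoch_s: 4.0
  pre_onset_s: 1.0
  rest_margin_s: 5.0
  p_ref: 0.01          # SL recurrence fraction
  ref_stride: 2
  r2_max: 0.1          # distance-bias QC bound
  require_equal_degree: false
  alpha: 0.05
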