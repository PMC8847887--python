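# Example run configuration (all sections optional; unknown keys rejected).
seed: 0
out_dir: results
log_level: INFO
simulation:
  variant: W
  n_per_class: 50
  length: 400
ews:
  bandwidths: [20, 30, 40]
  window_sizes: [40, 50, 60]
  indicators: [ACF1, SD, CV, RR, DR, AR1]
baseline:
  model_kind: random_forest
  n_estimators: 500
network:
  conv_filters: [128, 256, 128]
  conv_kernels: [8, 5, 3]
  lstm_units: 128
  fc_sizes: [128, 3]
training:
  epochs: 50
  batch_size: 64
  learning_rate: 0.001
experiment:
  n_trials: 25
  fractions: [0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0]
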