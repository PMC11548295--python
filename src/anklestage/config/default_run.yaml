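# Default end-to-end run configuration (desk-scale synthetic study).
#
# The per-stage cycle counts are deliberately imbalanced (stages II-IV
# under-represented) so the SMOTE balancing stage has real work to do;
# sessions are 8 s cycles at 60 Hz, windowed at 50 timesteps with a 50%
# stride (the best-performing stride fraction).
seed: 7
dataset:
  n_cycles_per_stage: {I: 24, II: 8, III: 8, IV: 8, V: 24}
  duration_s: 8.0
window:
  length: 50
  stride: 25
smote:
  k_neighbors: 5
  sampling_ratio: 1.0
  upsampling_rate: 100.0
split:
  train: 0.7
  valid: 0.15
  test: 0.15
tune:
  enabled: true
  n_agents: 8
  max_iteration: 5
train:
  epochs: 120
  batch_size: 16
  fitness_epochs: 30
model:
  n_classes: 5
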