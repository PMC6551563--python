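network:
  n_labels: 5
  depth: 3
  channels:
  - 8
  - 16
  - 32
  leaky_slope: 0.1
  dropout_rate: 0.2
  norm_kind: instance
  encoder_kind: residual
  fuse_multilevel: true
  upsample_kind: repeat
  decoder_mid_divisor: 2
  seed: 0
augment:
  rotation_max_deg: 10.0
  elastic_sigma: 16.0
  elastic_alpha: 4.0
  seed: 0
step_size: 0.001
beta1: 0.9
beta2: 0.999
adam_eps: 1.0e-07
epochs: 20
batch_size: 1
loss_epsilon: 0.001
copies_per_image: 2
augment_enabled: true
seed: 0
checkpoint_every: 0
select_best_validation: false
loss_includes_background: true
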