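# Small end-to-end pipeline configuration: `lufor all --config
# examples/config_small.yaml --out runs/small` finishes in a few minutes
# on one CPU. Omitted keys take their defaults; unknown keys are rejected.
seed: 1
output_dir: runs/small
scenes:
  height: 64
  width: 64
  n_scenes: 8
  annotated_fraction: 0.5
  test_fraction: 0.5
corruption:
  mislabel_fraction: 0.3
  drop_fraction: 0.3
model:
  depth: 2
  base_filters: 8
train:
  epochs: 6
  batch_size: 8
  patch_size: 32
active_learning:
  n_cycles: 1
  entropy_scale: nats
  entropy_threshold: 0.6
assessment:
  n_total: 150
  n_min: 1
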