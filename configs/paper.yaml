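# Study-scale configuration: 235-image corpus, published hyper-parameters
# (learning rate 0.01, momentum 0.9, dropout 0.5, 5000-iteration budget,
# 300-epoch schedule, verification every 1000 iterations, counting at
# P = 0.95 / I = 0.1).  Expect hours of CPU time for `report` (five splits).
seed: 0
out_dir: runs/paper
n_images: 235
scene:
  preset: standard
  rng_seed: 0
preprocess:
  resize: [256, 256]
  enhance: true
  augment_train: true
split:
  train_fraction: 0.8
train:
  base_learning_rate: 0.01
  momentum: 0.9
  dropout: 0.5
  batch_size: 100
  iteration_budget: 5000
  epochs: 300
  verification_period: 1000
nms:
  overlap_threshold: 0.3
evaluation:
  iou_threshold: 0.2
counting:
  confidence_threshold: 0.95
  overlap_area_ratio: 0.1
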