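# Desk-scale smoke configuration: small corpus, short schedule.
seed: 0
out_dir: runs/smoke
n_images: 50
scene:
  preset: easy
  rng_seed: 500
preprocess:
  resize: [256, 256]
  enhance: false
  augment_train: false
split:
  train_fraction: 0.8
train:
  iteration_budget: 200
  verification_period: 50
nms:
  overlap_threshold: 0.3
evaluation:
  iou_threshold: 0.2
counting:
  confidence_threshold: 0.95
  overlap_area_ratio: 0.1
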