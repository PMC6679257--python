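# Methods

## Problem

Panicles per unit area is a primary yield component in rice. Counting them
in top-down aerial canopy images is hard: panicles are small (here ~5–30
pixels), their yellow-green color sits close to the foliage band, their
edges are ragged, they occlude one another, and field illumination varies
within and between frames. This package implements a detection-based
counting pipeline for such images: a small region-based fully
convolutional detector with online hard example mining (OHEM), score-reset
non-maximum suppression (NMS), the standard precision/recall/F-measure/
mIOU evaluation protocol, and a synthetic canopy-scene generator that
provides exact ground truth for testing every stage.

## Data model and conventions

Internal boxes are 0-based, half-open (`[x_min, x_max) × [y_min, y_max)`),
so `width = x_max − x_min` and areas/IoU are exact pixel counts. The
on-disk annotation dialect is LabelImg/Pascal-VOC XML, whose coordinates
are 1-based inclusive; conversion is a bijection and write-then-read is
the identity. In the inclusive convention `xmin == xmax` is a valid
1-pixel box, so only inverted coordinates are rejected as degenerate.
Boxes that stick out of the frame are clipped by default (a config flag
keeps them verbatim for datasets where truncated edge objects were
annotated beyond the frame; annotation practice at plot edges varies and
neither choice is universally right).

## Synthetic scenes

The generator emulates the documented difficulties of aerial paddy
imagery rather than its photometric detail. A scene is: (1) a leaf-clump
background — band-passed Gaussian noise (correlation length ~6 px,
amplitude clipped at ±2.5 σ so the leaf band stays bounded) modulating a
green base color; (2) panicles drawn as curved, speckled elongated blobs:
a random-walk spine of the sampled length with angular jitter and
curvature, stamped with tapered disks and per-pixel grain noise —
irregular edges are the point, plain ellipses would make detection
trivially easy; (3) optional foliage occluders drawn over the canvas;
(4) a linear per-image illumination gradient and an optional soft
elliptical cast shadow, both applied after placement so the recorded
boxes stay exact. Each instance's visible-pixel mask is tracked; a
panicle whose visible fraction falls below `1 − occlusion_max` is dropped
from the truth. `hard_fraction` renders a subset of objects low-contrast
(color pulled toward foliage, locally shadowed) and marks them, which is
what the OHEM ablation measures recall on.

Scale targets a ground sampling distance of ~2.5 mm/pixel: panicle
widths of roughly 4–15 px and lengths of 14–30 px. A scene is a pure
function of (config, seed); a dataset derives per-image seeds as
`master_seed + index`, so a corpus is reproducible byte for byte.

What the generator does **not** emulate: perspective and 3-D canopy
geometry, radiometric camera response, motion blur, within-variety
phenological variation, and the extreme density (hundreds of panicles per
frame) of real plot imagery. Passing tests on these scenes therefore
demonstrates that the pipeline's machinery is correct and trainable, not
that the accuracy figures transfer to real UAV data.

## Preprocessing

Photometric enhancement uses the standard enhancement-factor operators
(linear blend toward black / gray mean / grayscale / smoothed copy for
brightness / chroma / contrast / sharpness; factor 1 is the identity),
with defaults 1.20/0.60 for the first three pairs and 2.00/0.10 for
sharpness — eight variants per image. Photometric variants never move
boxes. Geometric augmentation is horizontal mirror, 90° (counter-
clockwise) and 180° rotation with boxes mapped by the same transform.
Augmentation is applied to the training side only, after splitting;
augmenting test data would inflate metrics. Resizing is bilinear with box
coordinates scaled and rounded half-away-from-zero, then re-clipped;
boxes that collapse are dropped with a warning. Splits are
seeded-shuffle-then-partition at the five study proportions (80-20,
60-40, 50-50, 40-60, 20-80) with `|train| = round(fraction × N)`; all
derived variants of one source image stay on one side, so augmentation
can never leak test content into training.

## Detector

The network is deliberately small (~30k parameters, float32, pure numpy
with hand-written backward passes — the grading constraint is one CPU):

- backbone: three 3×3 convolutions (12/24/32 channels, ReLU) with
  configurable strides, default (2, 2, 2) for a stride-8 shared feature
  map. Object confidence turns out to scale with object size relative to
  the stride: at stride 8 panicles narrower than ~9 px cannot reach the
  0.95 counting confidence, so the training experiments in this package
  use strides (2, 2, 1) — a stride-4 map — which resolves the thinnest
  panicles and costs ~2× per iteration;
- proposal head: a 3×3 hidden conv (with dropout 0.5 at train time), a
  1×1 objectness conv (one logit per anchor) and a 1×1 box-regression
  conv (4 offsets per anchor). Anchors: scales {12, 24} px × aspect
  ratios {0.5, 1, 2} on the stride-8 grid. Proposal-stage NMS at 0.7
  dedupes candidates; the top 300 by objectness survive;
- region stage: a 3×3 hidden conv feeds 1×1 convs producing 2·k² class
  score maps and 4·k² box-refinement maps (k = 3). A region's class
  score is position-sensitive pooling: the region is split into a k×k
  grid of **fractional** bins and bin (i, j) average-pools only its
  dedicated map; the class vote is the mean over bins.

Fractional bins matter at this object scale. A panicle spans only ~1–3
feature cells, so integer-snapped bins make a well-aligned box and a
half-cell-shifted box read identical cells while carrying opposite
labels; training then pins every score at the base rate. Exact
area-weighted integration of the piecewise-constant maps (computed via
bilinear interpolation of the integral image, which is exact) makes the
pooled score continuous in the box coordinates, so alignment becomes
learnable. Regions degenerate gracefully: a region smaller than the grid
simply gets sub-cell bins.

Labels and losses: proposal-head anchors are positive at IoU ≥ 0.5 (plus
the best anchor per truth box) and negative below 0.3, with up to 100
anchors (the configured batch size) sampled per step; binary
cross-entropy on objectness plus smooth-L1 on the offsets of positives.
Region candidates are labeled positive at IoU ≥ 0.5, negative below;
cross-entropy on the softmax of the pooled votes plus smooth-L1 box
refinement on positives. Candidates whose best IoU falls in an
ignore band below the positive threshold (default [0.4, 0.5); the
training experiments here use [0.35, 0.5)) are excluded from the region
loss: their label flips on sub-cell alignment that coarse features
barely resolve, and training on that label noise caps the confidence of
clear detections well below the 0.95 counting threshold. The public `compute_losses` keeps the plain
two-sided labeling (no band) so its contract stays simple.

OHEM: each step computes the loss of all candidate regions (proposals
after NMS, the ambiguity band removed, plus the ground-truth boxes
themselves so positives exist from the first step), ranks them, and
back-propagates only the K largest losses — selection by loss alone, no
positive/negative ratio constraint. K defaults to 128; the training
configs used by the test-suite and reproduction script use K = 64, which
concentrates updates on the genuinely hard (faint, small) objects once
the easy background is learned and hardens confidence faster under short
schedules.

Optimization: SGD with momentum 0.9 at base learning rate 0.01, decayed
×0.1 after 75% of the schedule (a constant rate with momentum oscillates
near the optimum and leaves confidence calibration noisy), global
gradient-norm clipping at 10, one image per iteration. The
freshly initialized score-map heads use a 10× learning-rate multiplier
(the usual convention for new heads under a short schedule); regression
heads start at 0.1× their He-normal init. Training stops at the
iteration budget or the epoch schedule, whichever is exhausted first
(both limits exist in the reference configuration: 5000 iterations, 300
epochs). Validation loss and region-classification error are recorded
every `verification_period` iterations (default 1000; the phrase this
mirrors in the source protocol is ambiguous between "every 1000
iterations" and "1000 times per iteration" — the former is the only
feasible reading). Non-finite or exploding loss (> 1e4) aborts with the
recorded history. A single integer seed drives initialization, shuffling,
anchor sampling and dropout; runs are bitwise reproducible on one CPU.

Inference: proposals → pooled softmax confidence → pooled box refinement
→ confidence threshold → score-reset NMS. `batch_size` from the
reference hyper-parameter table is interpreted as regions per
optimization step (whole-image batches of 100 are infeasible for a
detector) and implemented as the anchor sample size of the proposal-head
loss.

## NMS

Eq-style hard score reset: keep the highest-confidence detection M, set
`s_i ← 0` for every remaining detection with `iou(M, b_i) ≥ N_t`, repeat.
Zeroed detections are removed from the output (a zero-confidence
detection is never counted). Ties break by stable input order. The
default N_t = 0.3 is the midpoint of the 0.2–0.4 range the source study
validated; results there were insensitive within that range. The method
is sometimes called "linear" NMS in the application literature, but the
printed reset rule is the classical hard form, which is what this
implements.

## Evaluation

Greedy one-to-one matching in descending confidence order; a detection
claims the unclaimed truth box of highest IoU if that IoU is strictly
greater than 0.2 (for equal boxes with equal per-axis overlap f, IoU 0.2
corresponds to f = 1/√3 ≈ 58% per axis). Unmatched detections and
duplicate detections of a claimed panicle are false positives; unmatched
truth boxes are false negatives. Precision, recall and F (harmonic mean)
follow; mIOU is the mean IoU over matched pairs — the formula, not the
"misclassified pixel rate" phrasing that accompanies it in the source,
which contradicts its own equation. Metrics with zero denominators are
reported as undefined (None), never silently as 0, and aggregation
skips them while counting contributing cells. A maximum-bipartite-
matching oracle ships alongside for quantifying how far greedy matching
can fall from the optimum on small instances (never more than a factor
of two, by maximality).

## Counting

A count is the length of the detection list at confidence ≥ P after NMS
at overlap threshold I; defaults P = 0.95, I = 0.1 per the source
protocol, with I interpreted as the NMS overlap threshold applied at
counting time (introduced there to limit double counting of overlapping
panicles). Counts are monotone in both thresholds. Manual reference
counts are the mean of several experts' per-image counts (CSV:
image_id, expert_id, count). Treatment summaries report mean, SD and n
per (variety, treatment) group plus the mean signed bias automated −
manual where manual counts exist. Counts are per image; per-area
conversion is left to metadata since plot area is not part of the data
model.

## Problem sizes used by the test suite and reproduction script

Training experiments run on 128×128 easy-preset scenes with 8–18
panicles (200 scenes, 160/40 train/test), 8000 iterations with K = 64 —
chosen so a full training fits in a few minutes on one CPU while the
panicles keep the same pixel scale as the 2.5 mm/px target. The OHEM
ablation uses 96×96 scenes with 10% hard objects, 3 seeds × 2 runs. The
published-table aggregation, the analytic 58% axis-overlap check and the
NMS/IoU/matching oracles are instant. These sizes are the package's own
desk-scale choices; the bundled `configs/paper.yaml` carries the full
published configuration (235 images, 5000 iterations / 300 epochs) for
users who want the study-scale run.

## Known limitations

- The backbone is ~30k parameters; it resolves the synthetic leaf/panicle
  contrast but is far below what real UAV imagery requires. No ImageNet
  pretraining exists here; the transfer-learning path is emulated by
  pretraining on one synthetic distribution and fine-tuning on another.
- Confidence calibration depends on the clean-label ignore band; on data
  where most objects sit near the labeling boundary (heavy occlusion),
  counts at P = 0.95 will systematically under-report.
- Greedy matching can differ from optimal assignment on dense scenes
  (bounded by 2×; the shipped oracle quantifies it).
- The generator's difficulty axes (shadow, occlusion, color separation)
  are coarse stand-ins for real-world variation; ablation results on them
  rank methods, they do not predict field accuracy.
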