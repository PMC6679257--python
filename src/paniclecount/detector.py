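"""A minimal region-based fully convolutional detector for panicle counting.

Two-stage, single-class, fully convolutional and small enough to train on
one CPU:

1. a shared backbone (three stride-2 convolutions, stride-8 feature map)
   feeds a region-proposal head that scores a dense anchor grid and
   regresses anchor-to-object box offsets;
2. position-sensitive score maps (k x k grid, one dedicated map per class
   and grid cell, plus class-agnostic box-refinement maps) are pooled over
   each proposal to produce its class score and refined box — there are no
   per-region fully connected layers.

Training is SGD with momentum in a joint end-to-end manner, with online
hard example mining (OHEM): every step computes the loss of all candidate
regions, ranks them, and back-propagates only through the K regions with
the largest loss.  This relaxes any fixed positive/negative sampling ratio
and concentrates learning on occluded, shadowed and low-contrast objects.

Redundant detections are removed by score-reset NMS (:mod:`paniclecount.nms`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations_io import AnnotatedImage, BoundingBox, DatasetManifest, boxes_to_array
from .nets import (
    Conv2D,
    Dropout,
    SGDMomentum,
    bce_with_logits,
    sigmoid,
    smooth_l1,
    smooth_l1_grad,
    softmax,
)
from .nms import Detection, NmsConfig, iou_matrix, suppress, suppress_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "ProposalSet",
    "RegionLoss",
    "TrainState",
    "generate_proposals",
    "position_sensitive_score",
    "compute_losses",
    "select_hard_examples",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

STRIDE = 8  # backbone downsampling factor


@dataclass(frozen=True)
class HyperParams:
    """Training hyper-parameters.

    The optimization defaults (learning rate 0.01, momentum 0.9, dropout
    0.5, batch of 100 regions, 5000-iteration budget, 300-epoch schedule,
    verification every 1000 iterations) follow the published configuration
    of the improved region-based detector this package implements;
    whichever of the iteration budget and the epoch schedule is exhausted
    first stops training.  ``batch_size`` is the number of anchors sampled
    per step for the proposal-head loss; second-stage losses are computed
    on every candidate region and OHEM then keeps the ``ohem_k`` hardest.
    """

    base_learning_rate: float = 0.01
    momentum: float = 0.9
    dropout: float = 0.5
    batch_size: int = 100
    iteration_budget: int = 5000
    epochs: int = 300
    verification_period: int = 1000
    ohem_k: int = 128
    seed: int = 0
    # architecture
    channels: tuple[int, int, int] = (12, 24, 32)
    backbone_strides: tuple[int, int, int] = (2, 2, 2)
    ps_grid: int = 3  # k
    anchor_scales: tuple[float, ...] = (12.0, 24.0)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    proposal_count: int = 300
    proposal_nms_threshold: float = 0.7  # dedupe candidates before stage two
    region_ignore_band: tuple[float, float] = (0.4, 0.5)  # ambiguous-IoU band
    lr_decay_at: float = 0.75  # fraction of the schedule after which lr drops
    lr_decay_factor: float = 0.1
    use_ohem: bool = True
    loc_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("base_learning_rate", "momentum", "batch_size",
                     "iteration_budget", "epochs", "verification_period", "ohem_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    def with_(self, **kwargs) -> "HyperParams":
        return replace(self, **kwargs)

    @property
    def feature_stride(self) -> int:
        s1, s2, s3 = self.backbone_strides
        return s1 * s2 * s3


@dataclass
class ProposalSet:
    """Candidate regions from the proposal stage, clipped to the image."""

    boxes: np.ndarray  # (N, 4) x_min, y_min, x_max, y_max
    scores: np.ndarray  # (N,) objectness in [0, 1]
    image_id: str = ""

    @property
    def proposals(self) -> list[tuple[BoundingBox, float]]:
        return [
            (BoundingBox(*b), float(s)) for b, s in zip(self.boxes, self.scores)
        ]

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class RegionLoss:
    """Loss of one candidate region (classification + localization)."""

    region: BoundingBox
    loss: float
    label: str  # "panicle" | "background"
    cls_loss: float = 0.0
    loc_loss: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.loss) or self.loss < 0:
            raise ValueError(f"region loss must be finite and >= 0, got {self.loss}")


# ---------------------------------------------------------------------------
# box coding
# ---------------------------------------------------------------------------

def _encode(gt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """(tx, ty, tw, th) offsets of gt boxes relative to reference boxes."""
    rw = ref[:, 2] - ref[:, 0]
    rh = ref[:, 3] - ref[:, 1]
    rcx = ref[:, 0] + 0.5 * rw
    rcy = ref[:, 1] + 0.5 * rh
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gcx = gt[:, 0] + 0.5 * gw
    gcy = gt[:, 1] + 0.5 * gh
    return np.stack(
        [(gcx - rcx) / rw, (gcy - rcy) / rh, np.log(gw / rw), np.log(gh / rh)], axis=1
    )


def _decode(ref: np.ndarray, t: np.ndarray) -> np.ndarray:
    rw = ref[:, 2] - ref[:, 0]
    rh = ref[:, 3] - ref[:, 1]
    rcx = ref[:, 0] + 0.5 * rw
    rcy = ref[:, 1] + 0.5 * rh
    t = np.clip(t, -4.0, 4.0)
    cx = rcx + t[:, 0] * rw
    cy = rcy + t[:, 1] * rh
    w = rw * np.exp(t[:, 2])
    h = rh * np.exp(t[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _clip_boxes(boxes: np.ndarray, h: int, w: int) -> np.ndarray:
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0.0, float(w))
    out[:, 1::2] = np.clip(out[:, 1::2], 0.0, float(h))
    return out


def make_anchors(
    fh: int, fw: int, scales: Sequence[float], ratios: Sequence[float],
    stride: int = STRIDE,
) -> np.ndarray:
    """Dense anchor grid, (fh*fw*A, 4), cell-major then anchor-within-cell."""
    sizes = []
    for s in scales:
        for r in ratios:
            sizes.append((s * np.sqrt(1.0 / r), s * np.sqrt(r)))  # (w, h)
    sizes = np.array(sizes)
    cy = (np.arange(fh) + 0.5) * stride
    cx = (np.arange(fw) + 0.5) * stride
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)  # (fh*fw, 2) as (x, y)
    A = len(sizes)
    anchors = np.empty((len(centers), A, 4))
    anchors[:, :, 0] = centers[:, None, 0] - sizes[None, :, 0] / 2
    anchors[:, :, 1] = centers[:, None, 1] - sizes[None, :, 1] / 2
    anchors[:, :, 2] = centers[:, None, 0] + sizes[None, :, 0] / 2
    anchors[:, :, 3] = centers[:, None, 1] + sizes[None, :, 1] / 2
    return anchors.reshape(-1, 4)


# ---------------------------------------------------------------------------
# position-sensitive pooling
# ---------------------------------------------------------------------------

def _bin_edges(
    boxes: np.ndarray, k: int, fh: int, fw: int, stride: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional k-bin edges of each region on the feature grid.

    Returns (ys, xs), each (N, k+1), in continuous feature-cell units and
    clipped to the map.  Bins are fractional: a region narrower than the
    k x k grid simply gets sub-cell bins, which keeps the pooled score
    sensitive to sub-cell box alignment.
    """
    eps = 1e-3
    x0 = np.clip(boxes[:, 0] / stride, 0.0, fw - eps)
    y0 = np.clip(boxes[:, 1] / stride, 0.0, fh - eps)
    x1 = np.clip(boxes[:, 2] / stride, x0 + eps, float(fw))
    y1 = np.clip(boxes[:, 3] / stride, y0 + eps, float(fh))
    t = np.linspace(0.0, 1.0, k + 1)
    xs = x0[:, None] + (x1 - x0)[:, None] * t[None, :]
    ys = y0[:, None] + (y1 - y0)[:, None] * t[None, :]
    return ys, xs


def _integral_image(maps: np.ndarray) -> np.ndarray:
    """(h+1, w+1, C) cumulative integral of an (h, w, C) map stack."""
    S = maps.astype(np.float64).cumsum(axis=0).cumsum(axis=1)
    return np.pad(S, ((1, 0), (1, 0), (0, 0)))


def _sample_integral(S: np.ndarray, yf: np.ndarray, xf: np.ndarray) -> np.ndarray:
    """Evaluate the continuous integral at fractional coordinates.

    The running integral of a piecewise-constant field is piecewise
    bilinear, so bilinear interpolation of the cumulative image is exact.
    """
    h, w = S.shape[0] - 1, S.shape[1] - 1
    yf = np.clip(yf, 0.0, float(h))
    xf = np.clip(xf, 0.0, float(w))
    iy = np.minimum(yf.astype(int), h - 1)
    ix = np.minimum(xf.astype(int), w - 1)
    fy = (yf - iy)[..., None]
    fx = (xf - ix)[..., None]
    return (
        S[iy, ix] * (1 - fy) * (1 - fx)
        + S[iy, ix + 1] * (1 - fy) * fx
        + S[iy + 1, ix] * fy * (1 - fx)
        + S[iy + 1, ix + 1] * fy * fx
    )


def _pool_many(
    maps: np.ndarray, boxes: np.ndarray, k: int, stride: float
) -> np.ndarray:
    """Position-sensitive pooling of many regions -> (N, n_cls) votes.

    Bin (i, j) of a region average-pools (area-weighted, exact for the
    piecewise-constant map) only channel ``c*k*k + i*k + j``; the class
    vote is the mean over the k*k bins.
    """
    fh, fw, nch = maps.shape
    n_cls = nch // (k * k)
    if len(boxes) == 0:
        return np.zeros((0, n_cls))
    ys, xs = _bin_edges(boxes, k, fh, fw, stride)
    S = _integral_image(maps)
    corners = _sample_integral(S, ys[:, :, None], xs[:, None, :])  # (N, k+1, k+1, C)
    ints = (
        corners[:, 1:, 1:] - corners[:, :-1, 1:]
        - corners[:, 1:, :-1] + corners[:, :-1, :-1]
    )  # (N, k, k, C)
    areas = np.diff(ys, axis=1)[:, :, None] * np.diff(xs, axis=1)[:, None, :]
    means = ints / areas[..., None]  # (N, k, k, C)
    b = np.arange(k * k)
    chan = np.arange(n_cls)[None, :] * k * k + b[:, None]  # (k*k, n_cls)
    picked = means.reshape(len(boxes), k * k, nch)[:, b[:, None], chan]  # (N, k*k, n_cls)
    return picked.mean(axis=1)


def _pool_backward_many(
    dmaps: np.ndarray, boxes: np.ndarray, dscores: np.ndarray, k: int, stride: float
) -> None:
    """Scatter d(vote)/d(maps) of many regions into ``dmaps`` (in place).

    ``dscores`` is (N, n_cls); rows of zeros are skipped cheaply, so
    callers can pass the full region set with gradients only where needed.
    """
    fh, fw, nch = dmaps.shape
    ys_all, xs_all = _bin_edges(boxes, k, fh, fw, stride)
    for r in range(len(boxes)):
        if not dscores[r].any():
            continue
        _scatter_one(dmaps, ys_all[r], xs_all[r], dscores[r], k, fh, fw)


def _pool_backward_region(
    dmaps: np.ndarray, box: np.ndarray, dscores: np.ndarray, k: int, stride: float
) -> None:
    """Scatter d(vote)/d(maps) of one region into ``dmaps`` (in place)."""
    fh, fw, nch = dmaps.shape
    ys, xs = _bin_edges(box.reshape(1, 4), k, fh, fw, stride)
    _scatter_one(dmaps, ys[0], xs[0], np.asarray(dscores), k, fh, fw)


def _scatter_one(
    dmaps: np.ndarray, ys: np.ndarray, xs: np.ndarray, dscores: np.ndarray,
    k: int, fh: int, fw: int,
) -> None:
    n_cls = len(dscores)
    iy0, iy1 = int(ys[0]), min(int(np.ceil(ys[-1])), fh)
    ix0, ix1 = int(xs[0]), min(int(np.ceil(xs[-1])), fw)
    rows = np.arange(iy0, iy1)
    cols = np.arange(ix0, ix1)
    # overlap of each covered cell row/column with each bin row/column
    wy = np.clip(
        np.minimum(rows[None, :] + 1.0, ys[1:, None])
        - np.maximum(rows[None, :], ys[:-1, None]), 0.0, None,
    )  # (k, R)
    wx = np.clip(
        np.minimum(cols[None, :] + 1.0, xs[1:, None])
        - np.maximum(cols[None, :], xs[:-1, None]), 0.0, None,
    )  # (k, C)
    areas = np.diff(ys)[:, None] * np.diff(xs)[None, :]  # (k, k)
    vals = (wy.T[:, None, :, None] * wx.T[None, :, None, :]) / (
        k * k * areas
    )  # (R, C, k, k)
    vals = vals.reshape(len(rows), len(cols), k * k)
    chans = np.arange(n_cls)[None, :] * k * k + np.arange(k * k)[:, None]  # (k*k, n_cls)
    sub = dmaps[iy0:iy1, ix0:ix1]
    sub[:, :, chans] += vals[:, :, :, None] * dscores[None, None, None, :]


def position_sensitive_score(
    features: np.ndarray, region: BoundingBox | tuple, k: int
) -> np.ndarray:
    """Pool one region from position-sensitive maps; returns per-class scores.

    ``features`` is an (h, w, C*k*k) stack whose channel ``c*k*k + i*k + j``
    is the dedicated map of class ``c`` and grid cell ``(i, j)``.  The
    region (in feature-grid coordinates) is divided into a k x k grid of
    fractional bins; bin (i, j) average-pools only its own map (exact
    area-weighted integration of the piecewise-constant map), and the
    class score is the mean vote over the k*k bins.  With ``k = 1`` this
    reduces to plain average pooling over the region.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fh, fw, nch = features.shape
    if nch % (k * k) != 0:
        raise ValueError(f"channel count {nch} is not a multiple of k*k = {k * k}")
    reg = region.as_tuple() if isinstance(region, BoundingBox) else tuple(region)
    return _pool_many(features, np.asarray(reg, dtype=np.float64).reshape(1, 4),
                      k, stride=1.0)[0]


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _Net:
    """Backbone + proposal head + position-sensitive map heads."""

    def __init__(self, hp: HyperParams, rng: np.random.Generator) -> None:
        c1, c2, c3 = hp.channels
        s1, s2, s3 = hp.backbone_strides
        k = hp.ps_grid
        self.A = len(hp.anchor_scales) * len(hp.anchor_ratios)
        self.k = k
        self.stride = hp.feature_stride
        self.conv1 = Conv2D(3, c1, 3, s1, 1, relu=True, rng=rng)
        self.conv2 = Conv2D(c1, c2, 3, s2, 1, relu=True, rng=rng)
        self.conv3 = Conv2D(c2, c3, 3, s3, 1, relu=True, rng=rng)
        self.rpn_hidden = Conv2D(c3, c3, 3, 1, 1, relu=True, rng=rng)
        self.rpn_obj = Conv2D(c3, self.A, 1, 1, 0, relu=False, rng=rng)
        self.rpn_box = Conv2D(c3, 4 * self.A, 1, 1, 0, relu=False, rng=rng)
        self.ps_hidden = Conv2D(c3, c3, 3, 1, 1, relu=True, rng=rng)
        self.ps_cls = Conv2D(c3, 2 * k * k, 1, 1, 0, relu=False, rng=rng)
        self.ps_reg = Conv2D(c3, 4 * k * k, 1, 1, 0, relu=False, rng=rng)
        # gentle start for the regression and map heads
        self.rpn_box.W *= 0.1
        self.ps_reg.W *= 0.1
        # freshly initialized score-map heads learn at 10x the base rate,
        # the usual convention for new heads under a short schedule
        self.ps_cls.lr_mult = 10.0
        self.ps_reg.lr_mult = 10.0
        self.dropout = Dropout(hp.dropout)

    def layers(self):
        return [self.conv1, self.conv2, self.conv3, self.rpn_hidden,
                self.rpn_obj, self.rpn_box, self.ps_hidden, self.ps_cls,
                self.ps_reg]

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for layer in self.layers():
            layer.zero_grad()

    def forward(self, pixels: np.ndarray, train: bool, rng: np.random.Generator | None):
        x = pixels.astype(np.float32) / np.float32(255.0) - np.float32(0.5)
        f = self.conv3.forward(
            self.conv2.forward(self.conv1.forward(x, train), train), train
        )
        rh = self.rpn_hidden.forward(f, train)
        rh = self.dropout.forward(rh, rng, train and rng is not None)
        ph = self.ps_hidden.forward(f, train)
        return {
            "feat": f,
            "obj": self.rpn_obj.forward(rh, train),
            "box": self.rpn_box.forward(rh, train),
            "ps_cls": self.ps_cls.forward(ph, train),
            "ps_reg": self.ps_reg.forward(ph, train),
        }

    def backward(self, dobj, dbox, dps_cls, dps_reg):
        drh = self.rpn_obj.backward(dobj) + self.rpn_box.backward(dbox)
        drh = self.dropout.backward(drh)
        dfeat = self.rpn_hidden.backward(drh)
        dph = self.ps_cls.backward(dps_cls) + self.ps_reg.backward(dps_reg)
        dfeat += self.ps_hidden.backward(dph)
        self.conv1.backward(self.conv2.backward(self.conv3.backward(dfeat)))


@dataclass
class TrainState:
    """Trained parameters plus the training trajectory."""

    net: _Net
    hp: HyperParams
    iteration: int = 0
    history: list[dict] = field(default_factory=list)  # per verification period
    loss_curve: list[float] = field(default_factory=list)  # per iteration


# ---------------------------------------------------------------------------
# proposal stage
# ---------------------------------------------------------------------------

def _proposals_from_maps(
    obj: np.ndarray, box: np.ndarray, hp: HyperParams, image_hw: tuple[int, int],
    min_size: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    fh, fw, A = obj.shape
    anchors = make_anchors(fh, fw, hp.anchor_scales, hp.anchor_ratios,
                           stride=hp.feature_stride)
    scores = sigmoid(obj.reshape(-1))
    deltas = box.reshape(-1, 4)
    decoded = _clip_boxes(_decode(anchors, deltas), image_hw[0], image_hw[1])
    w = decoded[:, 2] - decoded[:, 0]
    h = decoded[:, 3] - decoded[:, 1]
    ok = (w >= min_size) & (h >= min_size)
    decoded, scores = decoded[ok], scores[ok]
    # pre-select, deduplicate overlapping candidates, then cap at top-N
    order = np.argsort(-scores, kind="stable")[: 4 * hp.proposal_count]
    decoded, scores = decoded[order], scores[order]
    keep = suppress_arrays(decoded, scores, hp.proposal_nms_threshold,
                           max_keep=hp.proposal_count)
    return decoded[keep], scores[keep]


def generate_proposals(
    image: AnnotatedImage, state: TrainState,
    anchor_spec: tuple[Sequence[float], Sequence[float]] | None = None,
) -> ProposalSet:
    """Run the proposal stage on one image; top-N candidates by objectness."""
    hp = state.hp
    if anchor_spec is not None:
        hp = hp.with_(anchor_scales=tuple(anchor_spec[0]),
                      anchor_ratios=tuple(anchor_spec[1]))
        if len(anchor_spec[0]) * len(anchor_spec[1]) != state.net.A:
            raise ValueError("anchor_spec size incompatible with trained proposal head")
    maps = state.net.forward(image.pixels, train=False, rng=None)
    boxes, scores = _proposals_from_maps(maps["obj"], maps["box"], hp, image.size)
    return ProposalSet(boxes=boxes, scores=scores, image_id=image.image_id)


# ---------------------------------------------------------------------------
# losses and OHEM
# ---------------------------------------------------------------------------

def _region_losses(
    ps_cls: np.ndarray, ps_reg: np.ndarray, prop_boxes: np.ndarray,
    gt: np.ndarray, hp: HyperParams, pos_iou: float = 0.5,
) -> dict:
    """Per-region classification + localization losses and backward cache."""
    k = hp.ps_grid
    n = len(prop_boxes)
    stride = hp.feature_stride
    cls_scores = _pool_many(ps_cls, prop_boxes, k, stride=stride)  # (n, 2)
    reg_scores = _pool_many(ps_reg, prop_boxes, k, stride=stride)  # (n, 4)

    if len(gt):
        ious = iou_matrix(prop_boxes, gt)
        max_iou = ious.max(axis=1)
        match = ious.argmax(axis=1)
    else:
        max_iou = np.zeros(n)
        match = np.zeros(n, dtype=int)
    labels = (max_iou >= pos_iou).astype(int)

    probs = softmax(cls_scores, axis=1)
    cls_loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))

    loc_loss = np.zeros(n)
    targets = np.zeros((n, 4))
    diffs = np.zeros((n, 4))
    pos = labels == 1
    if pos.any() and len(gt):
        targets[pos] = _encode(gt[match[pos]], prop_boxes[pos])
        diffs[pos] = reg_scores[pos] - targets[pos]
        loc_loss[pos] = smooth_l1(diffs[pos]).sum(axis=1)

    total = cls_loss + hp.loc_weight * loc_loss
    if not np.all(np.isfinite(total)):
        raise FloatingPointError("non-finite region loss: training instability")
    return {
        "total": total, "cls": cls_loss, "loc": loc_loss, "labels": labels,
        "probs": probs, "diffs": diffs, "boxes": prop_boxes, "pos": pos,
    }


def compute_losses(
    state: TrainState, image: AnnotatedImage, proposals: ProposalSet,
    truth: Sequence[BoundingBox],
) -> list[RegionLoss]:
    """Loss of every candidate region against the ground truth.

    Regions are labelled positive when their best IoU with a truth box is
    at least 0.5; classification loss is cross-entropy and the smooth-L1
    localization loss applies to positives only.
    """
    maps = state.net.forward(image.pixels, train=False, rng=None)
    res = _region_losses(
        maps["ps_cls"], maps["ps_reg"], proposals.boxes,
        boxes_to_array(list(truth)), state.hp,
    )
    out = []
    for i, b in enumerate(proposals.boxes):
        out.append(
            RegionLoss(
                region=BoundingBox(*b),
                loss=float(res["total"][i]),
                label="panicle" if res["labels"][i] else "background",
                cls_loss=float(res["cls"][i]),
                loc_loss=float(res["loc"][i]),
            )
        )
    return out


def select_hard_examples(losses: Sequence[RegionLoss], k: int) -> list[RegionLoss]:
    """The k regions with the largest loss (all if fewer); ties keep input order.

    Selection is by loss alone — no positive/negative ratio constraint —
    which is what lets hard occluded objects dominate the update when the
    easy background has been learned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = np.array([r.loss for r in losses])
    order = np.argsort(-arr, kind="stable")[:k]
    return [losses[int(i)] for i in order]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _rpn_targets(anchors: np.ndarray, gt: np.ndarray,
                 pos_iou: float = 0.5, neg_iou: float = 0.3):
    m = len(anchors)
    labels = np.full(m, -1, dtype=int)
    targets = np.zeros((m, 4))
    if len(gt) == 0:
        labels[:] = 0
        return labels, targets
    ious = iou_matrix(anchors, gt)
    max_iou = ious.max(axis=1)
    match = ious.argmax(axis=1)
    labels[max_iou < neg_iou] = 0
    labels[max_iou >= pos_iou] = 1
    # every truth box claims its best-overlapping anchor
    best = ious.argmax(axis=0)
    ok = ious.max(axis=0) > 0.05
    labels[best[ok]] = 1
    pos = labels == 1
    targets[pos] = _encode(gt[match[pos]], anchors[pos])
    return labels, targets


def _training_step(
    net: _Net, hp: HyperParams, pixels: np.ndarray, gt: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    h, w = pixels.shape[:2]
    maps = net.forward(pixels, train=True, rng=rng)
    fh, fw, A = maps["obj"].shape
    anchors = make_anchors(fh, fw, hp.anchor_scales, hp.anchor_ratios,
                           stride=hp.feature_stride)
    labels, targets = _rpn_targets(anchors, gt)

    # --- proposal-head loss on a sampled anchor batch
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_pos = min(len(pos_idx), hp.batch_size // 2)
    if n_pos < len(pos_idx):
        pos_idx = rng.choice(pos_idx, size=n_pos, replace=False)
    n_neg = min(len(neg_idx), hp.batch_size - n_pos)
    if n_neg < len(neg_idx):
        neg_idx = rng.choice(neg_idx, size=n_neg, replace=False)
    sample = np.concatenate([pos_idx, neg_idx]).astype(int)

    obj_flat = maps["obj"].reshape(-1)
    box_flat = maps["box"].reshape(-1, 4)
    y = labels[sample].astype(float)
    p = sigmoid(obj_flat[sample])
    rpn_cls = float(bce_with_logits(obj_flat[sample], y).mean())
    dobj = np.zeros_like(obj_flat)
    dobj[sample] = (p - y) / len(sample)

    dbox = np.zeros_like(box_flat)
    if len(pos_idx):
        diff = box_flat[pos_idx] - targets[pos_idx]
        rpn_loc = float(smooth_l1(diff).sum() / len(pos_idx))
        dbox[pos_idx] = hp.loc_weight * smooth_l1_grad(diff) / len(pos_idx)
    else:
        rpn_loc = 0.0

    # --- region stage: proposals plus the truth boxes themselves
    prop_boxes, _ = _proposals_from_maps(maps["obj"], maps["box"], hp, (h, w))
    if len(gt):
        # drop candidates inside the ambiguous-IoU band: their positive/
        # negative label flips on sub-cell alignment the features can
        # barely resolve, and training on them caps the confidence of
        # clear detections
        lo, hi = hp.region_ignore_band
        band = iou_matrix(prop_boxes, gt).max(axis=1)
        prop_boxes = prop_boxes[(band < lo) | (band >= hi)]
        prop_boxes = np.concatenate([prop_boxes, gt], axis=0)
    res = _region_losses(maps["ps_cls"], maps["ps_reg"], prop_boxes, gt, hp)

    if hp.use_ohem:
        selected = np.argsort(-res["total"], kind="stable")[: hp.ohem_k]
    else:
        selected = np.arange(len(prop_boxes))
    region_loss = float(res["total"][selected].mean()) if len(selected) else 0.0

    dps_cls = np.zeros_like(maps["ps_cls"])
    dps_reg = np.zeros_like(maps["ps_reg"])
    nsel = max(len(selected), 1)
    k = hp.ps_grid
    n_regions = len(prop_boxes)
    dcls_scores = np.zeros((n_regions, 2))
    dcls_scores[selected] = res["probs"][selected]
    dcls_scores[selected, res["labels"][selected]] -= 1.0
    dcls_scores /= nsel
    dreg_scores = np.zeros((n_regions, 4))
    sel_pos = selected[res["pos"][selected]]
    dreg_scores[sel_pos] = (
        hp.loc_weight * smooth_l1_grad(res["diffs"][sel_pos]) / nsel
    )
    _pool_backward_many(dps_cls, prop_boxes, dcls_scores, k, hp.feature_stride)
    _pool_backward_many(dps_reg, prop_boxes, dreg_scores, k, hp.feature_stride)

    net.backward(
        dobj.reshape(maps["obj"].shape),
        dbox.reshape(maps["box"].shape),
        dps_cls,
        dps_reg,
    )
    total = rpn_cls + hp.loc_weight * rpn_loc + region_loss
    return {"loss": total, "rpn_cls": rpn_cls, "rpn_loc": rpn_loc,
            "region": region_loss}


def _validation_stats(net: _Net, hp: HyperParams, images: list) -> tuple[float, float]:
    """Mean region loss and region classification error on a validation set."""
    losses, errors, n = [], 0, 0
    for pixels, gt in images:
        maps = net.forward(pixels, train=False, rng=None)
        prop_boxes, _ = _proposals_from_maps(
            maps["obj"], maps["box"], hp, pixels.shape[:2]
        )
        if len(gt):
            prop_boxes = np.concatenate([prop_boxes, gt], axis=0)
        res = _region_losses(maps["ps_cls"], maps["ps_reg"], prop_boxes, gt, hp)
        losses.append(res["total"].mean())
        errors += int((res["probs"].argmax(axis=1) != res["labels"]).sum())
        n += len(prop_boxes)
    return float(np.mean(losses)), errors / max(n, 1)


def _as_training_pairs(
    data: DatasetManifest | Sequence[AnnotatedImage],
) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(data, DatasetManifest):
        images = data.load_images()
    else:
        images = list(data)
    return [(im.pixels, boxes_to_array(im.boxes)) for im in images]


def train(
    train_data: DatasetManifest | Sequence[AnnotatedImage],
    hp: HyperParams = HyperParams(),
    val_data: DatasetManifest | Sequence[AnnotatedImage] | None = None,
    init_state: TrainState | None = None,
    divergence_limit: float = 1e4,
) -> TrainState:
    """Train the detector end to end with SGD + momentum and OHEM.

    Each step processes one image: proposals are generated, the loss of
    every candidate region is computed, and only the ``ohem_k`` highest-loss
    regions contribute second-stage gradients.  Validation loss and region
    classification error are recorded every ``verification_period``
    iterations.  Training stops when either the iteration budget or the
    epoch schedule is exhausted, whichever comes first.

    ``init_state`` warm-starts from previously trained parameters (the
    transfer-learning path: pretrain on one scene distribution, fine-tune
    on another).
    """
    pairs = _as_training_pairs(train_data)
    if not pairs:
        raise ValueError("empty training set")
    val_pairs = _as_training_pairs(val_data) if val_data is not None else pairs[:5]

    rng = np.random.default_rng(hp.seed)
    if init_state is not None:
        net = init_state.net
    else:
        net = _Net(hp, rng)
    opt = SGDMomentum(net.params(), hp.base_learning_rate, hp.momentum)
    state = TrainState(net=net, hp=hp)

    total_iters = min(hp.iteration_budget, hp.epochs * len(pairs))
    it = 0
    while it < total_iters:
        order = rng.permutation(len(pairs))
        for idx in order:
            if it >= total_iters:
                break
            opt.zero_grad()
            stats = _training_step(net, hp, pairs[idx][0], pairs[idx][1], rng)
            if not np.isfinite(stats["loss"]) or stats["loss"] > divergence_limit:
                raise RuntimeError(
                    f"training diverged at iteration {it}: loss {stats['loss']:.3g}; "
                    f"history={state.history}"
                )
            opt.step()
            state.loss_curve.append(stats["loss"])
            it += 1
            if it == int(hp.lr_decay_at * total_iters):
                opt.lr = hp.base_learning_rate * hp.lr_decay_factor
                logger.info("iter %d: learning rate decayed to %g", it, opt.lr)
            if it % hp.verification_period == 0:
                vloss, verr = _validation_stats(net, hp, val_pairs)
                state.history.append(
                    {"iteration": it, "val_loss": vloss, "val_error": verr}
                )
                logger.info("iter %d: val loss %.4f, val error %.4f", it, vloss, verr)
    state.iteration = it
    return state


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict(
    image: AnnotatedImage,
    state: TrainState,
    confidence_threshold: float = 0.5,
    nms_config: NmsConfig | None = NmsConfig(),
    refine_boxes: bool = True,
) -> list[Detection]:
    """Detect panicles in one image.

    Proposals are scored by position-sensitive pooling, refined by the
    pooled box offsets, thresholded on softmax confidence and deduplicated
    by score-reset NMS.  Pass ``nms_config=None`` to skip suppression (the
    raw thresholded set is then a superset of the suppressed one).
    """
    hp = state.hp
    maps = state.net.forward(image.pixels, train=False, rng=None)
    h, w = image.size
    prop_boxes, _ = _proposals_from_maps(maps["obj"], maps["box"], hp, (h, w))
    if len(prop_boxes) == 0:
        return []
    k = hp.ps_grid
    stride = hp.feature_stride
    probs = softmax(_pool_many(maps["ps_cls"], prop_boxes, k, stride), axis=1)[:, 1]
    boxes = prop_boxes
    if refine_boxes:
        deltas = _pool_many(maps["ps_reg"], prop_boxes, k, stride)
        boxes = _clip_boxes(_decode(prop_boxes, deltas), h, w)
    keep = (probs >= confidence_threshold) & (boxes[:, 2] - boxes[:, 0] >= 1.0) \
        & (boxes[:, 3] - boxes[:, 1] >= 1.0)
    detections = [
        Detection(BoundingBox(*b), float(np.clip(s, 0.0, 1.0)))
        for b, s in zip(boxes[keep], probs[keep])
    ]
    if nms_config is not None:
        detections = suppress(detections, nms_config)
    else:
        detections.sort(key=lambda d: -d.score)
    return detections


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_LAYER_NAMES = ["conv1", "conv2", "conv3", "rpn_hidden", "rpn_obj", "rpn_box",
                "ps_hidden", "ps_cls", "ps_reg"]


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Parameter archive (.npz) plus a JSON sidecar with run metadata."""
    path = Path(path)
    arrays = {}
    for name in _LAYER_NAMES:
        layer = getattr(state.net, name)
        arrays[f"{name}.W"] = layer.W
        arrays[f"{name}.b"] = layer.b
    np.savez(path, **arrays)
    sidecar = {
        "hyper_params": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in state.hp.__dict__.items()},
        "iteration": state.iteration,
        "history": state.history,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> TrainState:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    hp_kwargs = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in sidecar["hyper_params"].items()
    }
    hp = HyperParams(**hp_kwargs)
    net = _Net(hp, np.random.default_rng(hp.seed))
    with np.load(path) as data:
        for name in _LAYER_NAMES:
            layer = getattr(net, name)
            layer.W = data[f"{name}.W"]
            layer.b = data[f"{name}.b"]
            layer.dW = np.zeros_like(layer.W)
            layer.db = np.zeros_like(layer.b)
    return TrainState(net=net, hp=hp, iteration=sidecar["iteration"],
                      history=sidecar["history"])
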