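"""Intersection-over-union and score-reset non-maximum suppression.

The suppression rule is the hard score-reset form: starting from the
highest-confidence detection M, every remaining detection b_i with
``iou(M, b_i) >= N_t`` has its confidence s_i reset to zero (and is
therefore removed from the output); detections with ``iou < N_t`` keep
their scores.  The overlap threshold N_t defaults to 0.3, the midpoint of
the 0.2-0.4 range validated for this kind of in-canopy organ detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations_io import BoundingBox

__all__ = ["Detection", "NmsConfig", "iou", "iou_matrix", "suppress", "suppress_arrays"]


@dataclass(frozen=True)
class Detection:
    """A detector output: box plus confidence score in [0, 1]."""

    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class NmsConfig:
    overlap_threshold: float = 0.3  # N_t

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise ValueError("overlap threshold must lie in [0, 1]")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes (half-open convention)."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) box arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def suppress_arrays(
    boxes: np.ndarray, scores: np.ndarray, overlap_threshold: float,
    max_keep: int | None = None,
) -> list[int]:
    """Greedy score-reset NMS on raw arrays; returns kept indices.

    Indices come back ordered by descending score; ties in score keep
    input order.  ``max_keep`` stops early once that many survivors have
    been collected (the remainder would be lower-scored anyway).
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64)
    n = len(boxes)
    if n == 0:
        return []
    order = np.argsort(-scores, kind="stable")
    b = boxes[order]
    areas = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    alive = np.ones(n, dtype=bool)
    keep: list[int] = []
    for i in range(n):
        if not alive[i]:
            continue
        keep.append(int(order[i]))
        if max_keep is not None and len(keep) >= max_keep:
            break
        rest = slice(i + 1, n)
        ix = np.minimum(b[i, 2], b[rest, 2]) - np.maximum(b[i, 0], b[rest, 0])
        iy = np.minimum(b[i, 3], b[rest, 3]) - np.maximum(b[i, 1], b[rest, 1])
        inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
        iou_row = inter / (areas[i] + areas[rest] - inter)
        alive[rest] &= iou_row < overlap_threshold
    return keep


def suppress(
    detections: list[Detection], config: NmsConfig = NmsConfig()
) -> list[Detection]:
    """Greedy score-reset NMS.

    Iteratively keeps the remaining detection with the highest confidence
    and zeroes out (removes) every other detection overlapping it with
    IoU >= N_t.  Ties in confidence are broken by stable input order.
    Output is sorted by descending score.
    """
    if not detections:
        return []
    boxes = np.array([d.box.as_tuple() for d in detections], dtype=np.float64)
    scores = np.array([d.score for d in detections], dtype=np.float64)
    keep = suppress_arrays(boxes, scores, config.overlap_threshold)
    return [detections[i] for i in keep]
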