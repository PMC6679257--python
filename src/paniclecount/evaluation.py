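"""Detection-truth matching and the precision/recall/F/mIOU protocol.

A detection counts as a true positive when it claims an unclaimed truth
box with IoU strictly greater than the matching threshold (0.2 by default
— for equal boxes with equal per-axis overlap fraction f this corresponds
to f = 1/sqrt(3), i.e. about 58% overlap along each axis).  False
positives are background called panicle *and* duplicate detections of an
already-claimed panicle; false negatives are missed panicles.

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)
    mIOU      = mean IoU over matched detection-truth pairs

Metrics with a zero denominator are reported as None (undefined), never
silently as zero, and aggregation skips them while reporting how many
cells contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .annotations_io import BoundingBox, boxes_to_array
from .nms import Detection, iou_matrix

__all__ = [
    "MatchResult",
    "MetricsRecord",
    "match_detections",
    "compute_metrics",
    "aggregate_splits",
    "render_report",
    "max_matching_tp",
    "axis_overlap_for_iou",
]

DEFAULT_IOU_THRESHOLD = 0.2


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[Detection, BoundingBox, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of matched pairs")


@dataclass
class MetricsRecord:
    precision: float | None
    recall: float | None
    f_measure: float | None
    m_iou: float | None
    split_tag: str = ""
    method_tag: str = ""


def match_detections(
    detections: Sequence[Detection],
    truth: Sequence[BoundingBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy one-to-one matching in descending confidence order.

    Each detection claims the not-yet-claimed truth box with which it has
    the highest IoU, provided that IoU is strictly greater than the
    threshold.  A second detection of an already-claimed truth box is a
    false positive (a duplicate detection), as is any detection matching
    no truth box.
    """
    det = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    t_arr = boxes_to_array(list(truth))
    d_arr = np.array(
        [detections[i].box.as_tuple() for i in det], dtype=np.float64
    ).reshape(-1, 4)
    claimed = np.zeros(len(truth), dtype=bool)
    pairs = []
    fp = 0
    if len(truth):
        ious = iou_matrix(d_arr, t_arr)
        for row, i in enumerate(det):
            avail = np.where(claimed, -1.0, ious[row])
            j = int(avail.argmax()) if len(avail) else -1
            if j >= 0 and avail[j] > iou_threshold:
                claimed[j] = True
                pairs.append((detections[i], truth[j], float(ious[row, j])))
            else:
                fp += 1
    else:
        fp = len(detections)
    return MatchResult(tp=len(pairs), fp=fp, fn=int((~claimed).sum()), pairs=pairs)


def compute_metrics(
    match: MatchResult, split_tag: str = "", method_tag: str = ""
) -> MetricsRecord:
    """Precision, recall, F-measure and mIOU from one match result."""
    p = match.tp / (match.tp + match.fp) if match.tp + match.fp > 0 else None
    r = match.tp / (match.tp + match.fn) if match.tp + match.fn > 0 else None
    if p is not None and r is not None and p + r > 0:
        f = 2.0 * p * r / (p + r)
    else:
        f = None
    m = float(np.mean([iou for _, _, iou in match.pairs])) if match.pairs else None
    return MetricsRecord(p, r, f, m, split_tag, method_tag)


def aggregate_splits(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """Per-method table across split proportions, with arithmetic-mean rows.

    Returns one row per (method, split) plus a ``mean`` row per method;
    ``n_splits`` counts the cells that contributed to each mean (undefined
    metrics are skipped, never imputed).
    """
    if not records:
        raise ValueError("no records to aggregate")
    rows = [
        {
            "method": r.method_tag,
            "split": r.split_tag,
            "precision": r.precision,
            "recall": r.recall,
            "f_measure": r.f_measure,
            "m_iou": r.m_iou,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    out = []
    metrics = ["precision", "recall", "f_measure", "m_iou"]
    for method, grp in df.groupby("method", sort=False):
        for _, row in grp.iterrows():
            out.append({**row.to_dict(), "n_splits": 1})
        mean_row = {"method": method, "split": "mean"}
        for mcol in metrics:
            vals = grp[mcol].dropna()
            mean_row[mcol] = vals.mean() if len(vals) else None
        mean_row["n_splits"] = int(grp[metrics].notna().any(axis=1).sum())
        out.append(mean_row)
    return pd.DataFrame(out, columns=["method", "split", *metrics, "n_splits"])


def render_report(table: pd.DataFrame) -> str:
    """Plain-text rendering of an aggregated per-split metrics table."""
    lines = [f"{'Method':<16}{'Split':<8}{'Prec':>7}{'Rec':>7}{'F':>7}{'mIOU':>7}"]
    for _, row in table.iterrows():
        vals = "".join(
            f"{row[c]:>7.3f}" if pd.notna(row[c]) else f"{'--':>7}"
            for c in ["precision", "recall", "f_measure", "m_iou"]
        )
        lines.append(f"{row['method']:<16}{row['split']:<8}{vals}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# oracles / analysis helpers
# ---------------------------------------------------------------------------

def max_matching_tp(
    detections: Sequence[Detection],
    truth: Sequence[BoundingBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> int:
    """Maximum achievable TP count (optimal bipartite assignment).

    Upper bound on the greedy matcher's TP; used to quantify how far the
    confidence-greedy convention can fall from the optimum on small
    instances.
    """
    if not detections or not truth:
        return 0
    d_arr = np.array([d.box.as_tuple() for d in detections]).reshape(-1, 4)
    ious = iou_matrix(d_arr, boxes_to_array(list(truth)))
    graph = csr_matrix(ious > iou_threshold)
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


def axis_overlap_for_iou(target_iou: float) -> float:
    """Per-axis overlap fraction f of two equal boxes giving a target IoU.

    Two identical axis-aligned boxes shifted so each axis overlaps fraction
    f have intersection f^2 and union 2 - f^2 (in units of one box area),
    so IoU = f^2 / (2 - f^2); solving for f gives
    f = sqrt(2 * iou / (1 + iou)).
    """
    if not (0.0 < target_iou <= 1.0):
        raise ValueError("target IoU must lie in (0, 1]")
    return float(np.sqrt(2.0 * target_iou / (1.0 + target_iou)))
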