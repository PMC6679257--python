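"""Panicle counting from detections and treatment-level summaries.

Counting is detection-based with no separate heuristic: a panicle count is
the number of detections surviving a high confidence threshold P (default
0.95) and non-maximum suppression at a tight overlap-area ratio I (default
0.1), the combination chosen to limit double counting of overlapping
panicles.  Manual reference counts, when available, are the mean of
several experts' counts per image (CSV schema: image_id, expert_id,
count).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotations_io import AnnotatedImage
from .detector import TrainState, predict
from .nms import NmsConfig

__all__ = [
    "CountingConfig",
    "CountRecord",
    "count_panicles",
    "read_manual_counts",
    "summarize_treatments",
]


@dataclass(frozen=True)
class CountingConfig:
    confidence_threshold: float = 0.95  # P
    overlap_area_ratio: float = 0.1  # I, NMS overlap threshold at counting time

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence threshold must lie in [0, 1]")
        if not (0.0 <= self.overlap_area_ratio <= 1.0):
            raise ValueError("overlap-area ratio must lie in [0, 1]")


@dataclass
class CountRecord:
    image_id: str
    automated_count: int
    manual_count: float | None = None  # mean of expert counts
    treatment_tag: str = ""
    variety_tag: str = ""

    def __post_init__(self) -> None:
        if self.automated_count < 0:
            raise ValueError("counts must be non-negative")


def count_panicles(
    image: AnnotatedImage,
    state: TrainState,
    config: CountingConfig = CountingConfig(),
    manual_count: float | None = None,
) -> CountRecord:
    """Count panicles in one image with the detection pipeline.

    The count is exactly the length of the post-threshold, post-NMS
    detection list.  Lowering P or raising I can only grow the count.
    """
    detections = predict(
        image,
        state,
        confidence_threshold=config.confidence_threshold,
        nms_config=NmsConfig(config.overlap_area_ratio),
    )
    return CountRecord(
        image_id=image.image_id,
        automated_count=len(detections),
        manual_count=manual_count,
        treatment_tag=str(image.meta.get("treatment", "")),
        variety_tag=str(image.meta.get("variety", "")),
    )


def read_manual_counts(path: str | Path) -> dict[str, float]:
    """Mean expert count per image from a (image_id, expert_id, count) CSV."""
    df = pd.read_csv(path)
    missing = {"image_id", "expert_id", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"manual-count CSV missing columns: {sorted(missing)}")
    return df.groupby("image_id")["count"].mean().to_dict()


def summarize_treatments(records: Sequence[CountRecord]) -> pd.DataFrame:
    """Per (variety, treatment) count summary with optional manual comparison.

    Returns mean, standard deviation and n of the automated counts per
    group; where manual counts are present, the mean signed bias
    (automated minus manual) is reported alongside.  Empty groups are
    simply absent from the output.
    """
    if not records:
        raise ValueError("no count records to summarize")
    df = pd.DataFrame(
        {
            "variety": r.variety_tag,
            "treatment": r.treatment_tag,
            "automated": r.automated_count,
            "manual": r.manual_count,
        }
        for r in records
    )
    rows = []
    for (variety, treatment), grp in df.groupby(["variety", "treatment"], sort=True):
        row = {
            "variety": variety,
            "treatment": treatment,
            "n": len(grp),
            "mean_count": grp["automated"].mean(),
            "sd_count": grp["automated"].std(ddof=1) if len(grp) > 1 else 0.0,
        }
        manual = grp["manual"].dropna()
        if len(manual):
            paired = grp.dropna(subset=["manual"])
            row["mean_manual"] = manual.mean()
            row["mean_bias"] = (paired["automated"] - paired["manual"]).mean()
        else:
            row["mean_manual"] = None
            row["mean_bias"] = None
        rows.append(row)
    return pd.DataFrame(rows)
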