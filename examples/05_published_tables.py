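"""Reproduce the published summary numbers from the bundled tables.

Feeds the published per-split detection metrics through the aggregation
utility (the column means are the headline figures of the original UAV
study) and summarizes the published per-plot panicle counts by fertilizer
treatment.  Also solves the small geometry identity relating the IoU
matching threshold to per-axis overlap.
"""

from paniclecount.counting import CountRecord, summarize_treatments
from paniclecount.evaluation import aggregate_splits, axis_overlap_for_iou, render_report
from paniclecount.reference_results import TREATMENT_COUNTS, split_metric_records

table = aggregate_splits(split_metric_records())
print(render_report(table[table["split"] == "mean"]))
print("mean rows: arithmetic means over the five train/test proportions; "
      "the improved detector leads every column\n")

records = [
    CountRecord(f"{v}_{t}_{i}", c, treatment_tag=t, variety_tag=v)
    for t, varieties in TREATMENT_COUNTS.items()
    for v, counts in varieties.items()
    for i, c in enumerate(counts)
]
summary = summarize_treatments(records)
print(summary.to_string(index=False))
print("untreated plots average fewer panicles/m^2 than fertilized ones "
      "for every variety\n")

f = axis_overlap_for_iou(0.2)
print(f"IoU 0.2 for equal boxes = {100 * f:.0f}% overlap along each axis "
      f"(f = {f:.4f}, since f^2/(2 - f^2) = 0.2)")
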