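"""Published benchmark values for the UAV rice-panicle detection study.

These tables reproduce, as plain data, the per-split detection metrics and
the per-plot panicle counts reported for the original (unreleased) UAV
field dataset.  They exist so the aggregation and summary utilities can be
exercised against real published numbers: feeding the per-split rows
through :func:`paniclecount.evaluation.aggregate_splits` reproduces the
quoted column means (e.g. mean precision 0.868 for the improved
region-based detector), and the treatment counts drive the counting-report
example.

Note: a few published F-measure cells are not exactly the harmonic mean of
their row's precision and recall; the cells are kept verbatim here, while
:func:`~paniclecount.evaluation.compute_metrics` always reports the exact
harmonic mean for metrics it computes itself.
"""

from __future__ import annotations

import pandas as pd

from .evaluation import MetricsRecord

__all__ = [
    "SPLIT_METRICS",
    "TREATMENT_COUNTS",
    "split_metric_records",
    "treatment_count_frame",
]

# (method, train-test split, precision, recall, F-measure, mIOU)
SPLIT_METRICS: list[tuple[str, str, float, float, float, float]] = [
    ("alexnet",       "80-20", 0.731, 0.699, 0.711, 0.821),
    ("alexnet",       "60-40", 0.684, 0.672, 0.681, 0.808),
    ("alexnet",       "50-50", 0.626, 0.615, 0.619, 0.810),
    ("alexnet",       "40-60", 0.622, 0.596, 0.603, 0.796),
    ("alexnet",       "20-80", 0.592, 0.583, 0.590, 0.784),
    ("vggnet",        "80-20", 0.819, 0.819, 0.807, 0.803),
    ("vggnet",        "60-40", 0.821, 0.831, 0.828, 0.796),
    ("vggnet",        "50-50", 0.805, 0.825, 0.817, 0.793),
    ("vggnet",        "40-60", 0.792, 0.808, 0.801, 0.785),
    ("vggnet",        "20-80", 0.773, 0.787, 0.781, 0.783),
    ("inception_v3",  "80-20", 0.834, 0.879, 0.854, 0.799),
    ("inception_v3",  "60-40", 0.835, 0.871, 0.862, 0.804),
    ("inception_v3",  "50-50", 0.827, 0.824, 0.820, 0.851),
    ("inception_v3",  "40-60", 0.801, 0.806, 0.805, 0.846),
    ("inception_v3",  "20-80", 0.793, 0.785, 0.791, 0.831),
    ("improved_rfcn", "80-20", 0.866, 0.904, 0.896, 0.925),
    ("improved_rfcn", "60-40", 0.897, 0.901, 0.891, 0.892),
    ("improved_rfcn", "50-50", 0.872, 0.897, 0.875, 0.889),
    ("improved_rfcn", "40-60", 0.861, 0.870, 0.865, 0.886),
    ("improved_rfcn", "20-80", 0.844, 0.843, 0.843, 0.843),
]

# per-plot panicle counts (panicles per square meter, 10 plots each) for
# three rice varieties under three nitrogen fertilizer regimes
TREATMENT_COUNTS: dict[str, dict[str, list[int]]] = {
    "no_treatment": {
        "XH34":  [5217, 5563, 5218, 5119, 5534, 5168, 5197, 5984, 6107, 5547],
        "XH40":  [5718, 5213, 5549, 5769, 5421, 5533, 5697, 6078, 6124, 6057],
        "XH166": [5533, 5478, 5961, 5311, 5426, 5697, 5321, 5514, 5321, 5578],
    },
    "early_treatment": {
        "XH34":  [6210, 6587, 6412, 6622, 6478, 6271, 6978, 6389, 6584, 6397],
        "XH40":  [6648, 6913, 6875, 6389, 6472, 6196, 6389, 6145, 6089, 6552],
        "XH166": [6315, 6298, 6103, 6917, 6122, 6308, 6102, 6301, 6559, 6789],
    },
    "late_treatment": {
        "XH34":  [6987, 6359, 6555, 6471, 6216, 6333, 6987, 6874, 6222, 6315],
        "XH40":  [6321, 6975, 7004, 6894, 7105, 7056, 7059, 6981, 6781, 6145],
        "XH166": [6326, 6521, 6895, 6987, 7582, 7002, 6798, 6903, 6711, 6579],
    },
}


def split_metric_records() -> list[MetricsRecord]:
    """The published per-split metrics as MetricsRecord objects."""
    return [
        MetricsRecord(p, r, f, m, split_tag=split, method_tag=method)
        for method, split, p, r, f, m in SPLIT_METRICS
    ]


def treatment_count_frame() -> pd.DataFrame:
    """Long-form frame of the published counts (variety, treatment, plot, count)."""
    rows = []
    for treatment, varieties in TREATMENT_COUNTS.items():
        for variety, counts in varieties.items():
            for plot, count in enumerate(counts, start=1):
                rows.append(
                    {"variety": variety, "treatment": treatment,
                     "plot": plot, "count": count}
                )
    return pd.DataFrame(rows)
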