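"""Matching, metric formulas, aggregation against published values."""

from __future__ import annotations

import numpy as np
import pytest

from paniclecount.annotations_io import BoundingBox
from paniclecount.evaluation import (
    MatchResult,
    MetricsRecord,
    aggregate_splits,
    axis_overlap_for_iou,
    compute_metrics,
    match_detections,
    max_matching_tp,
)
from paniclecount.nms import Detection, iou
from paniclecount.reference_results import split_metric_records


def _det(x0, y0, x1, y1, s):
    return Detection(BoundingBox(x0, y0, x1, y1), s)


def _random_instance(rng, n_det, n_truth, extent=60.0):
    truth = []
    for _ in range(n_truth):
        x0, y0 = rng.uniform(0, extent, 2)
        truth.append(BoundingBox(x0, y0, x0 + rng.uniform(2, 15), y0 + rng.uniform(2, 15)))
    dets = []
    for _ in range(n_det):
        if truth and rng.uniform() < 0.7:
            base = truth[rng.integers(len(truth))]
            dx, dy = rng.normal(0, 3, 2)
            dets.append(
                Detection(
                    BoundingBox(base.x_min + dx, base.y_min + dy,
                                base.x_max + dx, base.y_max + dy).clip((100, 100))
                    or BoundingBox(0, 0, 1, 1),
                    float(rng.uniform()),
                )
            )
        else:
            x0, y0 = rng.uniform(0, extent, 2)
            dets.append(
                Detection(BoundingBox(x0, y0, x0 + rng.uniform(2, 15),
                                      y0 + rng.uniform(2, 15)), float(rng.uniform()))
            )
    return dets, truth


class TestMatching:
    def test_exact_detections_all_true_positive(self):
        truth = [BoundingBox(0, 0, 10, 10), BoundingBox(30, 30, 40, 45)]
        dets = [Detection(b, 0.9) for b in truth]
        m = match_detections(dets, truth)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)
        assert all(i == 1.0 for _, _, i in m.pairs)

    def test_duplicate_detection_is_false_positive(self):
        truth = [BoundingBox(0, 0, 10, 10)]
        dets = [_det(0, 0, 10, 10, 0.9), _det(1, 1, 11, 11, 0.8)]
        assert iou(dets[1].box, truth[0]) > 0.2
        m = match_detections(dets, truth)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_below_threshold_is_miss_plus_false_positive(self):
        truth = [BoundingBox(0, 0, 10, 10)]
        det = _det(8, 8, 18, 18, 0.9)  # IoU = 4/196 < 0.2
        assert iou(det.box, truth[0]) < 0.2
        m = match_detections([det], truth)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_threshold_is_strict(self):
        """IoU exactly at the threshold does not count as positive."""
        truth = [BoundingBox(0, 0, 10, 10)]  # area 100
        det = _det(0, 0, 10, 2, 0.9)  # nested, inter 20, union 100: IoU = 0.2
        assert iou(det.box, truth[0]) == 0.2
        m = match_detections([det], truth, iou_threshold=0.2)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_conservation_invariants_random(self, rng):
        for _ in range(150):
            dets, truth = _random_instance(rng, int(rng.integers(0, 12)),
                                           int(rng.integers(0, 8)))
            m = match_detections(dets, truth)
            assert m.tp + m.fn == len(truth)
            assert m.tp + m.fp == len(dets)
            assert m.tp == len(m.pairs)
            assert all(i > 0.2 for _, _, i in m.pairs)

    def test_greedy_close_to_maximum_matching(self, rng):
        """Greedy TP never exceeds the optimum and stays within a factor 2."""
        for _ in range(120):
            dets, truth = _random_instance(rng, int(rng.integers(1, 10)),
                                           int(rng.integers(1, 10)))
            m = match_detections(dets, truth)
            best = max_matching_tp(dets, truth)
            assert m.tp <= best
            assert m.tp >= int(np.ceil(best / 2))

    def test_threshold_monotonicity(self, rng):
        dets, truth = _random_instance(rng, 10, 8)
        tps = [match_detections(dets, truth, t).tp for t in (0.1, 0.2, 0.4, 0.6)]
        assert tps == sorted(tps, reverse=True)


class TestMetrics:
    def test_direct_substitution(self):
        m = MatchResult(3, 1, 1, [(None, None, 0.5)] * 3)
        r = compute_metrics(m)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.75)
        assert r.f_measure == pytest.approx(0.75)

    def test_perfect_match_all_ones(self):
        m = MatchResult(4, 0, 0, [(None, None, 1.0)] * 4)
        r = compute_metrics(m)
        assert (r.precision, r.recall, r.f_measure, r.m_iou) == (1.0, 1.0, 1.0, 1.0)

    def test_f_equals_p_when_p_equals_r(self):
        m = MatchResult(6, 2, 2, [(None, None, 0.8)] * 6)
        r = compute_metrics(m)
        assert r.precision == r.recall == pytest.approx(r.f_measure)

    def test_undefined_metrics_are_none_not_zero(self):
        r = compute_metrics(MatchResult(0, 0, 3, []))
        assert r.precision is None
        assert r.recall == 0.0
        assert r.f_measure is None
        assert r.m_iou is None

    def test_f_between_min_and_max(self, rng):
        for _ in range(100):
            tp = int(rng.integers(1, 20))
            fp = int(rng.integers(0, 20))
            fn = int(rng.integers(0, 20))
            r = compute_metrics(MatchResult(tp, fp, fn, [(None, None, 0.5)] * tp))
            assert min(r.precision, r.recall) - 1e-12 <= r.f_measure
            assert r.f_measure <= max(r.precision, r.recall) + 1e-12


class TestAggregation:
    def test_published_column_means(self):
        """Per-split cells reproduce the quoted column means exactly."""
        table = aggregate_splits(split_metric_records())
        means = table[table["split"] == "mean"].set_index("method")
        rfcn = means.loc["improved_rfcn"]
        assert rfcn["precision"] == pytest.approx(0.868, abs=1e-12)
        assert rfcn["recall"] == pytest.approx(0.883, abs=1e-12)
        assert rfcn["f_measure"] == pytest.approx(0.874, abs=1e-12)
        assert rfcn["m_iou"] == pytest.approx(0.887, abs=1e-12)
        assert means.loc["alexnet", "precision"] == pytest.approx(0.651, abs=1e-12)
        assert means.loc["vggnet", "precision"] == pytest.approx(0.802, abs=1e-12)
        assert means.loc["vggnet", "recall"] == pytest.approx(0.814, abs=1e-12)
        assert means.loc["vggnet", "m_iou"] == pytest.approx(0.792, abs=1e-12)
        assert means.loc["inception_v3", "precision"] == pytest.approx(0.818, abs=1e-12)
        assert means.loc["inception_v3", "recall"] == pytest.approx(0.833, abs=1e-12)

    def test_single_record_mean_is_itself(self):
        rec = MetricsRecord(0.5, 0.6, 0.545, 0.7, "80-20", "m")
        table = aggregate_splits([rec])
        mean = table[table["split"] == "mean"].iloc[0]
        assert mean["precision"] == pytest.approx(0.5)
        assert mean["n_splits"] == 1

    def test_undefined_cells_skipped_with_count(self):
        recs = [
            MetricsRecord(0.8, 0.8, 0.8, 0.8, "80-20", "m"),
            MetricsRecord(None, None, None, None, "20-80", "m"),
        ]
        table = aggregate_splits(recs)
        mean = table[table["split"] == "mean"].iloc[0]
        assert mean["precision"] == pytest.approx(0.8)


def test_axis_overlap_analytic_solution():
    """f^2 / (2 - f^2) = 0.2 has the solution f = 1/sqrt(3) ~ 58%."""
    f = axis_overlap_for_iou(0.2)
    assert f == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-12)
    assert f ** 2 / (2.0 - f ** 2) == pytest.approx(0.2, abs=1e-12)
    assert round(100 * f) == 58
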