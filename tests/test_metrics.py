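import numpy as np
import pytest

from conftest import random_boxes
from flexdetect.io_formats import Box
from flexdetect.metrics import (average_precision, box_iou, confusion_matrix,
                                evaluate, map50, match_detections,
                                precision_recall)


def brute_force_ap(preds: list[Box], gts_count: int, tp_flags: np.ndarray,
                   confs: np.ndarray) -> float:
    """Independent AP oracle: explicit O(n^2) threshold sweep + envelope."""
    order = np.lexsort((np.arange(len(confs)), -confs))
    tp = tp_flags[order]
    points = []
    for k in range(1, len(tp) + 1):
        tp_k = tp[:k].sum()
        points.append((tp_k / gts_count, tp_k / k))
    ap = 0.0
    r_prev = 0.0
    for i, (r, p) in enumerate(points):
        p_env = max(pp for rr, pp in points[i:])  # envelope from the right
        if r > r_prev:
            ap += (r - r_prev) * p_env
            r_prev = r
    return ap


class TestMatching:
    def test_perfect_predictions_all_tp(self, rng):
        gts = random_boxes(rng, 5)
        preds = [Box(b.cls, b.cx, b.cy, b.w, b.h, 0.9) for b in gts]
        m = match_detections(preds, gts)
        assert m.n_tp == 5 and m.n_fp == 0 and m.n_fn == 0

    def test_no_predictions_all_fn(self, rng):
        gts = random_boxes(rng, 4)
        m = match_detections([], gts)
        assert m.n_tp == 0 and m.n_fn == 4

    def test_worked_two_gt_three_pred(self):
        gts = [Box(0, 0.2, 0.2, 0.1, 0.1), Box(0, 0.6, 0.6, 0.1, 0.1)]
        preds = [Box(0, 0.2, 0.2, 0.1, 0.1, 0.9),
                 Box(0, 0.9, 0.9, 0.05, 0.05, 0.8),   # FP
                 Box(0, 0.6, 0.6, 0.1, 0.1, 0.7)]
        m = match_detections(preds, gts)
        assert (m.n_tp, m.n_fp, m.n_fn) == (2, 1, 0)

    def test_class_must_match(self):
        gts = [Box(0, 0.5, 0.5, 0.2, 0.2)]
        preds = [Box(1, 0.5, 0.5, 0.2, 0.2, 0.9)]
        m = match_detections(preds, gts)
        assert m.n_tp == 0 and m.n_fp == 1 and m.n_fn == 1

    def test_each_gt_matched_at_most_once(self):
        gt = [Box(0, 0.5, 0.5, 0.2, 0.2)]
        preds = [Box(0, 0.5, 0.5, 0.2, 0.2, c) for c in (0.9, 0.8, 0.7)]
        m = match_detections(preds, gt)
        assert m.n_tp == 1 and m.n_fp == 2

    def test_counting_invariants_on_random_scenes(self, rng):
        for _ in range(50):
            gts = random_boxes(rng, int(rng.integers(0, 6)))
            preds = random_boxes(rng, int(rng.integers(0, 8)), with_conf=True)
            m = match_detections(preds, gts)
            assert m.n_tp + m.n_fn == len(gts)
            assert m.n_tp + m.n_fp == len(preds)
            assert m.n_tp <= min(len(preds), len(gts))


class TestPrecisionRecall:
    def test_plug_in_values(self):
        m = match_detections([], [])
        m.tp = np.array([True] * 5 + [False] * 3)
        m.conf = np.linspace(1, 0.3, 8)
        m.pred_cls = np.zeros(8, int)
        m.gt_matched = np.array([True] * 5 + [False] * 5)
        m.n_gt = 10
        p, r = precision_recall(m)
        assert p == pytest.approx(0.625)
        assert r == pytest.approx(0.5)

    def test_perfect_detector(self, rng):
        gts = random_boxes(rng, 3)
        preds = [Box(b.cls, b.cx, b.cy, b.w, b.h, 0.9) for b in gts]
        assert precision_recall(match_detections(preds, gts)) == (1.0, 1.0)

    def test_empty_conventions(self):
        p, r = precision_recall(match_detections([], []))
        assert (p, r) == (0.0, 1.0)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        ap = average_precision(np.array([True, True]), np.array([0.9, 0.8]), 2)
        assert ap == 1.0

    def test_worked_example(self):
        ap = average_precision(np.array([True, False, True]),
                               np.array([0.9, 0.8, 0.7]), 2)
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3), abs=1e-12)

    def test_all_false_positives(self):
        assert average_precision(np.array([False] * 4),
                                 np.linspace(1, 0.1, 4), 3) == 0.0

    def test_matches_brute_force_on_200_random_scenes(self, rng):
        for _ in range(200):
            n_gt = int(rng.integers(1, 8))
            n_pred = int(rng.integers(1, 12))
            tp = rng.random(n_pred) < 0.5
            # cap TPs at n_gt to keep flags feasible
            while tp.sum() > n_gt:
                tp[np.where(tp)[0][-1]] = False
            conf = rng.random(n_pred)
            if rng.random() < 0.3:  # exercise duplicate-confidence tie-break
                conf = np.round(conf, 1)
            fast = average_precision(tp, conf, n_gt)
            slow = brute_force_ap([], n_gt, tp, conf)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_invariant_to_duplicate_confidences(self):
        tp = np.array([True, False, True, False])
        conf = np.array([0.5, 0.5, 0.5, 0.5])
        # stable tie-break by prediction index: same as strictly ordered confs
        strict = np.array([0.9, 0.8, 0.7, 0.6])
        assert average_precision(tp, conf, 2) == pytest.approx(
            average_precision(tp, strict, 2), abs=1e-12)


class TestMap:
    def test_mean_identity(self):
        assert map50([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_reported_per_class_pattern(self):
        assert map50([0.745, 0.846, 0.810, 0.818]) == pytest.approx(0.80475)

    def test_empty(self):
        assert map50([]) == 0.0

    def test_iou_sweep_bounded_by_map50(self, rng):
        from flexdetect.metrics import map50_95
        gts = [random_boxes(rng, 3, n_classes=2) for _ in range(3)]
        preds = [[Box(b.cls, b.cx, b.cy, b.w, b.h, 0.9) for b in img]
                 for img in gts]
        # exact predictions: perfect at every threshold
        assert map50_95(gts, preds, ["a", "b"]) == pytest.approx(1.0)
        # jittered predictions: sweep mean cannot exceed the 0.5 value
        jit = [[Box(b.cls, min(b.cx + 0.015, 1.0), b.cy, b.w, b.h, 0.9)
                for b in img] for img in gts]
        sweep = map50_95(gts, jit, ["a", "b"])
        at50 = evaluate(gts, jit, ["a", "b"]).map50
        assert sweep <= at50 + 1e-12


class TestConfusionMatrix:
    def test_perfect_detector_diagonal(self, rng):
        gts = random_boxes(rng, 6, n_classes=3)
        preds = [Box(b.cls, b.cx, b.cy, b.w, b.h, 0.9) for b in gts]
        cm = confusion_matrix(preds, gts, 3)
        assert cm[:3, 3].sum() == 0 and cm[3, :3].sum() == 0
        assert np.trace(cm[:3, :3]) == 6

    def test_wrong_class_overlap_off_diagonal(self):
        gts = [Box(0, 0.5, 0.5, 0.2, 0.2)]
        preds = [Box(1, 0.5, 0.5, 0.2, 0.2, 0.9)]
        cm = confusion_matrix(preds, gts, 2)
        assert cm[1, 0] == 1
        assert cm.sum() == 1

    def test_no_predictions_mass_in_background_row(self, rng):
        gts = random_boxes(rng, 4, n_classes=2)
        cm = confusion_matrix([], gts, 2)
        assert cm[2, :2].sum() == 4 and cm.sum() == 4

    def test_low_confidence_dropped(self):
        gts = [Box(0, 0.5, 0.5, 0.2, 0.2)]
        preds = [Box(0, 0.5, 0.5, 0.2, 0.2, 0.1)]
        cm = confusion_matrix(preds, gts, 1, conf_thresh=0.25)
        assert cm[0, 0] == 0 and cm[1, 0] == 1


class TestEvaluate:
    def test_perfect_predictions_map_one(self, rng):
        gts = [random_boxes(rng, 3, n_classes=2) for _ in range(4)]
        preds = [[Box(b.cls, b.cx, b.cy, b.w, b.h, 0.9) for b in img]
                 for img in gts]
        report = evaluate(gts, preds, ["a", "b"])
        assert report.map50 == pytest.approx(1.0)
        assert report.precision == pytest.approx(1.0)
        assert report.recall == pytest.approx(1.0)

    def test_absent_class_excluded_and_reported(self, rng):
        gts = [[Box(0, 0.5, 0.5, 0.2, 0.2)]]
        preds = [[Box(0, 0.5, 0.5, 0.2, 0.2, 0.9)]]
        report = evaluate(gts, preds, ["a", "b"])
        assert report.classes_absent == ["b"]
        assert report.map50 == pytest.approx(1.0)

    def test_removing_prediction_no_crash_bounded_change(self, rng):
        gts = [random_boxes(rng, 3, n_classes=2) for _ in range(3)]
        preds = [[Box(b.cls, b.cx, b.cy, b.w, b.h, 0.9) for b in img]
                 for img in gts]
        full = evaluate(gts, preds, ["a", "b"]).map50
        preds[0] = preds[0][1:]
        partial = evaluate(gts, preds, ["a", "b"]).map50
        assert 0.0 <= partial <= full

    def test_mismatched_image_lists_rejected(self):
        with pytest.raises(ValueError):
            evaluate([[]], [[], []], ["a"])
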