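import itertools

import numpy as np
import pytest

from lizardtherm.detection import ClassLabel, Detection
from lizardtherm.frame_io import Rect
from lizardtherm.metrics import (
    ConfusionCounts,
    PRPoint,
    average_precision,
    evaluate,
    iou,
    match_detections,
    mean_average_precision,
    pr_curve,
    precision_recall_f1,
)


def rasterised_iou(a, b, span=20):
    """Pixel-count oracle: rasterise both boxes and count."""
    grid_a = np.zeros((span, span), bool)
    grid_b = np.zeros((span, span), bool)
    grid_a[a.y : a.y2, a.x : a.x2] = True
    grid_b[b.y : b.y2, b.x : b.x2] = True
    union = (grid_a | grid_b).sum()
    return (grid_a & grid_b).sum() / union


def grid_ap(points, n=200_000):
    """Fine-grid numeric integration of the monotone precision envelope."""
    rs = np.array([p.recall for p in points])
    ps = np.array([p.precision for p in points])
    grid = (np.arange(n) + 0.5) / n
    env = np.zeros(n)
    for r, p in zip(rs, ps):
        env[grid <= r] = np.maximum(env[grid <= r], p)
    return env.mean()


def brute_force_counts(preds, gt_boxes, thr):
    """Exhaustive best assignment (max TPs) on tiny instances."""
    best_tp = 0
    idx = range(len(gt_boxes))
    for k in range(min(len(preds), len(gt_boxes)), -1, -1):
        for pred_sub in itertools.combinations(range(len(preds)), k):
            for gt_perm in itertools.permutations(idx, k):
                if all(
                    iou(preds[i].box, gt_boxes[j]) >= thr
                    for i, j in zip(pred_sub, gt_perm)
                ):
                    best_tp = max(best_tp, k)
        if best_tp == k:
            break
    return best_tp


def _det(label, box, conf=1.0):
    return Detection(ClassLabel(label), box, conf)


class TestIou:
    def test_identical_and_disjoint(self):
        a = Rect(0, 0, 4, 4)
        assert iou(a, a) == 1.0
        assert iou(a, Rect(10, 10, 4, 4)) == 0.0

    def test_partial_overlap_fraction(self):
        # (0,0,2,2) vs (1,1,2,2): intersection 1, union 7
        a, b = Rect(0, 0, 2, 2), Rect(1, 1, 2, 2)
        assert iou(a, b) == pytest.approx(1 / 7)
        assert iou(a, b) == pytest.approx(rasterised_iou(a, b))

    def test_random_boxes_match_rasterised_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = Rect(*rng.integers(0, 10, 2), *rng.integers(1, 10, 2))
            b = Rect(*rng.integers(0, 10, 2), *rng.integers(1, 10, 2))
            assert iou(a, b) == pytest.approx(rasterised_iou(a, b))


class TestMatchDetections:
    def test_perfect_predictions(self):
        gts = [(ClassLabel.LIZARD, Rect(0, 0, 10, 10)), (ClassLabel.TAIL, Rect(20, 0, 8, 8))]
        preds = [_det(l.value, b, 0.9) for l, b in gts]
        c = match_detections(preds, gts, 0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 0)

    def test_low_iou_is_fp_plus_fn(self):
        gts = [(ClassLabel.LIZARD, Rect(0, 0, 10, 10))]
        preds = [_det("Lizard", Rect(7, 7, 10, 10), 0.9)]  # IoU ~ 0.047
        c = match_detections(preds, gts, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_class_mismatch_never_matches(self):
        gts = [(ClassLabel.TAIL, Rect(0, 0, 10, 10))]
        preds = [_det("Head", Rect(0, 0, 10, 10), 0.9)]
        c = match_detections(preds, gts, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_mixed_overlap_instance_matches_optimal_assignment(self):
        """3 preds vs 2 gts with mixed overlaps: greedy equals the optimum."""
        gts = [(ClassLabel.LIZARD, Rect(0, 0, 10, 10)),
               (ClassLabel.LIZARD, Rect(20, 0, 10, 10))]
        preds = [
            _det("Lizard", Rect(1, 1, 10, 10), 0.9),    # matches gt0
            _det("Lizard", Rect(21, 1, 10, 10), 0.8),   # matches gt1
            _det("Lizard", Rect(40, 0, 10, 10), 0.7),   # matches nothing
        ]
        c = match_detections(preds, gts, 0.5)
        assert c.tp == brute_force_counts(preds, [b for _, b in gts], 0.5) == 2
        assert (c.fp, c.fn) == (1, 0)

    def test_counts_conservation_and_oracle_bound_on_small_instances(self):
        """tp+fp = |preds|, tp+fn = |gts| always; greedy tp never exceeds the
        exhaustive-assignment optimum and stays within its 1/2-approximation
        guarantee."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            n_p, n_g = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            preds = [
                _det("Lizard", Rect(*rng.integers(0, 8, 2), *rng.integers(2, 8, 2)),
                     float(rng.random()))
                for _ in range(n_p)
            ]
            gts = [
                (ClassLabel.LIZARD, Rect(*rng.integers(0, 8, 2), *rng.integers(2, 8, 2)))
                for _ in range(n_g)
            ]
            c = match_detections(preds, gts, 0.5)
            assert c.tp + c.fp == n_p
            assert c.tp + c.fn == n_g
            assert c.tn == 0
            oracle_tp = brute_force_counts(preds, [b for _, b in gts], 0.5)
            assert c.tp <= oracle_tp
            assert c.tp >= (oracle_tp + 1) // 2


class TestPrecisionRecallF1:
    def test_direct_arithmetic(self):
        p, r, f1, flag = precision_recall_f1(ConfusionCounts(tp=3, fp=1, fn=2))
        assert (p, r) == (0.75, 0.6)
        assert f1 == pytest.approx(2 * 0.45 / 1.35)
        assert not flag

    def test_degenerate_zero_denominators(self):
        p, r, f1, flag = precision_recall_f1(ConfusionCounts(tp=0, fp=0, fn=5))
        assert (p, r, f1) == (0, 0, 0)
        assert flag

    def test_f1_equals_p_when_p_equals_r(self):
        for tp, fp in [(1, 1), (3, 1), (9, 1)]:
            p, r, f1, _ = precision_recall_f1(ConfusionCounts(tp=tp, fp=fp, fn=fp))
            assert p == r == pytest.approx(f1)


class TestAveragePrecision:
    def test_perfect_curve(self):
        pts = [PRPoint(r, 1.0) for r in (0.2, 0.5, 1.0)]
        assert average_precision(pts) == pytest.approx(1.0)

    def test_rectangle_area(self):
        pts = [PRPoint(0.5, 1.0), PRPoint(1.0, 0.0)]
        assert average_precision(pts) == pytest.approx(0.5)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            average_precision([])

    def test_random_curves_match_grid_integration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pts = [
                PRPoint(float(r), float(p))
                for r, p in zip(np.sort(rng.random(10)), rng.random(10))
            ]
            assert average_precision(pts) == pytest.approx(grid_ap(pts), abs=2e-5)

    def test_invariant_to_duplicate_points(self):
        pts = [PRPoint(0.3, 0.8), PRPoint(0.7, 0.5)]
        assert average_precision(pts + pts) == pytest.approx(average_precision(pts))

    def test_monotone_under_pointwise_precision_increase(self):
        rng = np.random.default_rng(3)
        rs = np.sort(rng.random(8))
        ps = rng.random(8)
        lower = [PRPoint(float(r), float(p)) for r, p in zip(rs, ps)]
        higher = [PRPoint(float(r), float(min(1, p + 0.1))) for r, p in zip(rs, ps)]
        assert average_precision(higher) >= average_precision(lower)


class TestMeanAveragePrecision:
    def test_mean_and_identity(self):
        assert mean_average_precision(
            {ClassLabel.LIZARD: 0.8, ClassLabel.TAIL: 0.6}
        ) == pytest.approx(0.7)
        assert mean_average_precision({ClassLabel.HEAD: 0.42}) == pytest.approx(0.42)

    def test_seven_random_classes_equal_direct_mean(self):
        rng = np.random.default_rng(4)
        aps = {label: float(rng.random()) for label in ClassLabel}
        assert mean_average_precision(aps) == pytest.approx(sum(aps.values()) / 7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision({})


class TestEvaluate:
    def test_perfect_predictions_score_one(self):
        gts = [
            (ClassLabel.LIZARD, Rect(0, 0, 20, 20)),
            (ClassLabel.TAIL, Rect(30, 0, 10, 10)),
        ]
        preds = [_det(l.value, b, 0.95) for l, b in gts]
        report = evaluate(preds, gts)
        for row in report.values():
            assert row.precision == row.recall == row.ap50 == 1.0
            assert row.ap50_95 == pytest.approx(1.0)

    def test_pr_curve_ranks_by_confidence(self):
        gts = [(ClassLabel.LIZARD, Rect(0, 0, 10, 10))]
        preds = [
            _det("Lizard", Rect(0, 0, 10, 10), 0.9),
            _det("Lizard", Rect(50, 50, 10, 10), 0.4),
        ]
        pts = pr_curve(preds, gts, ClassLabel.LIZARD)
        assert [(p.recall, p.precision) for p in pts] == [(1.0, 1.0), (1.0, 0.5)]
        assert average_precision(pts) == pytest.approx(1.0)
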