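"""Matching, DSB score, error taxonomy, mask loss, accuracy."""

import itertools

import numpy as np
import pytest

from nucseg import (
    InstanceSet,
    classification_accuracy,
    dsb_score,
    error_taxonomy,
    iou,
    mask_bce_loss,
    match_objects,
    precision_recall_f1,
)
from nucseg.metrics import DEFAULT_THRESHOLDS, DimensionError

from conftest import random_instances


def square(r0, c0, size, canvas=(32, 32)):
    yy, xx = np.mgrid[r0 : r0 + size, c0 : c0 + size]
    return np.stack([yy.ravel(), xx.ravel()], axis=1)


def brute_force_counts(pred: InstanceSet, gt: InstanceSet, t: float) -> tuple[int, int, int]:
    """Exhaustive max-TP one-to-one pairing (oracle for small instances)."""
    m = np.zeros((len(gt), len(pred)))
    for i in range(len(gt)):
        gi = gt.object_mask(i)
        for j in range(len(pred)):
            m[i, j] = iou(gi, pred.object_mask(j))
    best = 0
    n_gt, n_pred = m.shape
    small, large = (range(n_gt), range(n_pred)) if n_gt <= n_pred else (range(n_pred), range(n_gt))
    for perm in itertools.permutations(large, len(list(small))):
        tp = 0
        for a, b in zip(small, perm):
            i, j = (a, b) if n_gt <= n_pred else (b, a)
            if m[i, j] > t:
                tp += 1
        best = max(best, tp)
    return best, n_pred - best, n_gt - best


class TestIoU:
    def test_identity_and_disjoint(self):
        m = np.zeros((8, 8), dtype=bool)
        m[:4, :4] = True
        assert iou(m, m) == 1.0
        assert iou(m, ~m) == 0.0

    def test_shifted_square_worked_example(self):
        a = np.zeros((12, 20), dtype=bool)
        b = np.zeros((12, 20), dtype=bool)
        a[:10, :10] = True
        b[:10, 2:12] = True
        assert iou(a, b) == pytest.approx(80 / 120)

    def test_both_empty_is_zero(self):
        z = np.zeros((4, 4), dtype=bool)
        assert iou(z, z) == 0.0

    def test_canvas_mismatch(self):
        with pytest.raises(DimensionError):
            iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestMatching:
    def test_perfect_prediction(self, toy_data):
        _, s = toy_data[0]
        t = match_objects(s, s)
        assert np.all(t.tp == len(s)) and np.all(t.fp == 0) and np.all(t.fn == 0)

    def test_empty_prediction(self):
        gt = InstanceSet(16, 16, [square(0, 0, 3, (16, 16)), square(5, 5, 3, (16, 16)), square(10, 10, 3, (16, 16))])
        t = match_objects(InstanceSet(16, 16), gt)
        assert np.all(t.tp == 0) and np.all(t.fp == 0) and np.all(t.fn == 3)

    def test_tp_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = match_objects(random_instances(rng), random_instances(rng))
            assert np.all(np.diff(t.tp) <= 0)
            assert np.all(t.tp + t.fn == t.fn[0] + t.tp[0])

    def test_greedy_equals_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pred, gt = random_instances(rng), random_instances(rng)
            table = match_objects(pred, gt)
            for k, t in enumerate(table.thresholds):
                assert (table.tp[k], table.fp[k], table.fn[k]) == brute_force_counts(pred, gt, t)


class TestDSBScore:
    def test_perfect_scores_one(self, toy_data):
        _, s = toy_data[0]
        assert dsb_score(s, s) == pytest.approx(1.0, abs=1e-39)

    def test_shifted_square_scores_point_four(self):
        gt = InstanceSet(12, 20, [square(0, 0, 10, (12, 20))])
        pred = InstanceSet(12, 20, [square(0, 2, 10, (12, 20))])
        assert iou(pred.object_mask(0), gt.object_mask(0)) == pytest.approx(2 / 3)
        assert dsb_score(pred, gt) == pytest.approx(0.4)

    def test_empty_prediction_scores_zero(self):
        gt = InstanceSet(8, 8, [square(0, 0, 4, (8, 8))])
        assert dsb_score(InstanceSet(8, 8), gt) == pytest.approx(0.0)

    def test_both_empty_scores_one(self):
        assert dsb_score(InstanceSet(8, 8), InstanceSet(8, 8)) == 1.0

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(3)
        pred, gt = random_instances(rng, max_objects=4), random_instances(rng, max_objects=4)
        perm = list(reversed(range(len(pred))))
        pred2 = InstanceSet(pred.height, pred.width, [pred.objects[i] for i in perm], [i + 10 for i in range(len(pred))])
        assert dsb_score(pred, gt) == pytest.approx(dsb_score(pred2, gt))


class TestPrecisionRecallF1:
    def test_perfect(self, toy_data):
        _, s = toy_data[0]
        rep = precision_recall_f1([(s, s)])
        assert rep.mAP == pytest.approx(1.0) and rep.mAR == pytest.approx(1.0) and rep.mF1 == pytest.approx(1.0)

    def test_one_gt_two_preds(self):
        canvas = (20, 40)
        gt = InstanceSet(*canvas, [square(0, 0, 10, canvas)])
        # first pred overlaps gt at IoU 9/11 ~ 0.818; second is far away
        pred = InstanceSet(*canvas, [square(0, 1, 10, canvas), square(5, 25, 5, canvas)])
        rep = precision_recall_f1([(pred, gt)])
        n_hit = sum(1 for t in DEFAULT_THRESHOLDS if 90 / 110 > t)
        assert rep.mAP == pytest.approx(0.5 * n_hit / 10)
        assert rep.mAR == pytest.approx(1.0 * n_hit / 10)
        assert rep.mF1 == pytest.approx((2 * 0.5 / 1.5) * n_hit / 10)

    def test_scores_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            rep = precision_recall_f1([(random_instances(rng), random_instances(rng))])
            for v in (rep.dsb_score, rep.mAP, rep.mAR, rep.mF1):
                assert 0.0 <= v <= 1.0


class TestErrorTaxonomy:
    def test_perfect_prediction_all_zero(self, toy_data):
        _, s = toy_data[0]
        assert error_taxonomy(s, s).as_tuple() == (0, 0, 0, 0)

    def test_split_detected(self):
        canvas = (20, 20)
        gt = InstanceSet(*canvas, [square(0, 0, 10, canvas)])  # 100 px
        left = np.array([[r, c] for r in range(10) for c in range(5)])
        right = np.array([[r, c] for r in range(10) for c in range(5, 10)])
        pred = InstanceSet(*canvas, [left, right])  # 50 px each
        errs = error_taxonomy(pred, gt)
        assert errs.split == 1 and errs.missed == 0

    def test_merge_detected(self):
        canvas = (20, 30)
        # one prediction covering two GT objects at 100%/100% of each
        g1 = square(0, 0, 6, canvas)
        g2 = square(0, 10, 6, canvas)
        pred_mask = np.array([[r, c] for r in range(6) for c in range(16)])
        errs = error_taxonomy(InstanceSet(*canvas, [pred_mask]), InstanceSet(*canvas, [g1, g2]))
        assert errs.merged == 1

    def test_missed_and_false_detection(self):
        canvas = (20, 20)
        gt = InstanceSet(*canvas, [square(0, 0, 5, canvas)])
        pred = InstanceSet(*canvas, [square(12, 12, 5, canvas)])
        errs = error_taxonomy(pred, gt)
        assert errs.missed == 1 and errs.false_detected == 1


class TestMaskLoss:
    def test_perfect_prediction_near_zero(self):
        y = (np.arange(64).reshape(8, 8) % 2).astype(float)
        assert mask_bce_loss(y, y) <= 1e-6

    def test_uniform_half_equals_ln2(self):
        y = np.zeros((8, 8))
        y[::2] = 1
        assert mask_bce_loss(np.full((8, 8), 0.5), y) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.random((8, 8))
            y = (rng.random((8, 8)) < 0.5).astype(float)
            ref = 0.0
            for i in range(8):
                for j in range(8):
                    pij = min(max(p[i, j], 1e-12), 1 - 1e-12)
                    ref -= y[i, j] * np.log(pij) + (1 - y[i, j]) * np.log(1 - pij)
            ref /= 64
            assert mask_bce_loss(p, y) == pytest.approx(ref, abs=1e-12)

    def test_dim_mismatch(self):
        with pytest.raises(DimensionError):
            mask_bce_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestClassificationAccuracy:
    @pytest.mark.parametrize(
        "calls,truth,expected",
        [
            ([1, 1, 0], [1, 1, 0], 1.0),
            ([0, 0, 0], [1, 1, 1], 0.0),
            ([1] * 36 + [0] * 28, [1] * 36 + [1] * 28, 36 / 64),
        ],
    )
    def test_values(self, calls, truth, expected):
        assert classification_accuracy(calls, truth) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classification_accuracy([], [])
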