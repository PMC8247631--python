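"""Object matching and segmentation scores.

Implements the 2018 Data Science Bowl evaluation: IoU-based object matching
over thresholds 0.5..0.95 (step 0.05), the DSB score
``mean_t TP/(TP+FP+FN+eps)``, threshold-averaged precision/recall/F1
(mAP/mAR/mF1), the per-ROI binary cross-entropy mask loss, a plain
classification accuracy, and the four-way error taxonomy
(missed / false detection / split / merge).

A predicted object is a "hit" when its IoU with a ground-truth object is
*strictly* greater than the threshold; pairing is greedy by descending IoU
with uniqueness (for t >= 0.5 at most one candidate per object can exceed the
threshold, so greedy pairing is optimal).  The small epsilon added to every
denominator is 1e-40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import InstanceSet

EPSILON = 1e-40
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.951, 0.05), 2))

#: significant-overlap levels for the split/merge taxonomy: at least 30% of
#: the covered object when exactly two objects contribute, 15% when more.
SPLIT_MERGE_MAJOR = 0.30
SPLIT_MERGE_MINOR = 0.15


class DimensionError(ValueError):
    """Canvas shapes of the two arguments disagree."""


@dataclass
class MatchTable:
    """Per-threshold TP/FP/FN counts plus the underlying IoU pairs."""

    thresholds: tuple[float, ...]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (gt label, pred label, IoU)

    def __post_init__(self) -> None:
        self.tp = np.asarray(self.tp, dtype=np.int64)
        self.fp = np.asarray(self.fp, dtype=np.int64)
        self.fn = np.asarray(self.fn, dtype=np.int64)


@dataclass
class ScoreReport:
    """Aggregate and per-image DSB-score / mAP / mAR / mF1."""

    dsb_score: float
    mAP: float
    mAR: float
    mF1: float
    per_image: list[dict] = field(default_factory=list)
    epsilon: float = EPSILON


@dataclass
class ErrorCounts:
    missed: int = 0
    false_detected: int = 0
    split: int = 0
    merged: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.missed, self.false_detected, self.split, self.merged)


# ---------------------------------------------------------------------------
# IoU and matching
# ---------------------------------------------------------------------------


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union (Jaccard index) of two binary masks.

    Returns 0 when both masks are empty, by convention.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = a.sum() + b.sum() - inter
    if union == 0:
        return 0.0
    return float(inter) / float(union)


def _pairwise_iou(pred: InstanceSet, gt: InstanceSet) -> np.ndarray:
    """(n_gt, n_pred) IoU matrix via sorted flat-index intersection."""
    if pred.shape != gt.shape:
        raise DimensionError(f"canvas mismatch: {pred.shape} vs {gt.shape}")
    gt_idx = [gt.ravelled(i) for i in range(len(gt))]
    pr_idx = [pred.ravelled(j) for j in range(len(pred))]
    m = np.zeros((len(gt), len(pred)))
    for i, gi in enumerate(gt_idx):
        for j, pj in enumerate(pr_idx):
            inter = np.intersect1d(gi, pj, assume_unique=True).size
            if inter:
                m[i, j] = inter / (gi.size + pj.size - inter)
    return m


def match_objects(pred: InstanceSet, gt: InstanceSet, thresholds=DEFAULT_THRESHOLDS) -> MatchTable:
    """Greedy one-to-one matching by descending IoU at each threshold.

    A pair counts as a TP iff IoU > t (strict).  Ties on equal IoU are broken
    by (gt label, pred label) order.  Unmatched ground truth objects are FN,
    unmatched predictions FP.
    """
    thresholds = tuple(float(t) for t in thresholds)
    m = _pairwise_iou(pred, gt)
    n_gt, n_pred = m.shape
    # candidate pairs sorted by (-iou, gt label, pred label)
    cand = [
        (m[i, j], gt.labels[i], pred.labels[j], i, j)
        for i in range(n_gt)
        for j in range(n_pred)
        if m[i, j] > 0
    ]
    cand.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for iou_val, glab, plab, i, j in cand:
        if i in used_gt or j in used_pred:
            continue
        used_gt.add(i)
        used_pred.add(j)
        pairs.append((glab, plab, float(iou_val)))
    pair_ious = np.array([p[2] for p in pairs]) if pairs else np.zeros(0)
    tp = np.array([(pair_ious > t).sum() for t in thresholds], dtype=np.int64)
    fp = n_pred - tp
    fn = n_gt - tp
    return MatchTable(thresholds, tp, fp, fn, pairs)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def dsb_score(pred: InstanceSet, gt: InstanceSet, thresholds=DEFAULT_THRESHOLDS) -> float:
    """Per-image DSB score: mean over thresholds of TP/(TP+FP+FN+eps).

    An image with neither predictions nor ground truth scores 1.0 (a perfect
    prediction of an empty image is not an error).
    """
    if len(pred) == 0 and len(gt) == 0:
        return 1.0
    table = match_objects(pred, gt, thresholds)
    scores = table.tp / (table.tp + table.fp + table.fn + EPSILON)
    return float(scores.mean())


def dsb_score_set(pairs: list[tuple[InstanceSet, InstanceSet]], thresholds=DEFAULT_THRESHOLDS) -> float:
    """Set-level DSB score: mean of per-image scores."""
    if not pairs:
        raise ValueError("empty image set")
    return float(np.mean([dsb_score(p, g, thresholds) for p, g in pairs]))


def precision_recall_f1(
    pred_gt_pairs: list[tuple[InstanceSet, InstanceSet]] | tuple[InstanceSet, InstanceSet],
    thresholds=DEFAULT_THRESHOLDS,
) -> ScoreReport:
    """Threshold-averaged precision/recall/F1 (and DSB score), then image-averaged.

    Per threshold t: ``precision = TP/(TP+FP+eps)``, ``recall = TP/(TP+FN+eps)``
    and ``F1 = 2 p r/(p+r+eps)``; each is averaged over the thresholds per
    image and the set-level value is the mean over images.  Note mF1 is the
    threshold-averaged harmonic mean, not the harmonic mean of mAP and mAR.
    """
    if isinstance(pred_gt_pairs, tuple) and isinstance(pred_gt_pairs[0], InstanceSet):
        pred_gt_pairs = [pred_gt_pairs]  # type: ignore[list-item]
    per_image = []
    for pred, gt in pred_gt_pairs:
        if len(pred) == 0 and len(gt) == 0:
            per_image.append({"dsb_score": 1.0, "mAP": 1.0, "mAR": 1.0, "mF1": 1.0})
            continue
        t = match_objects(pred, gt, thresholds)
        prec = t.tp / (t.tp + t.fp + EPSILON)
        rec = t.tp / (t.tp + t.fn + EPSILON)
        f1 = 2 * prec * rec / (prec + rec + EPSILON)
        dsb = t.tp / (t.tp + t.fp + t.fn + EPSILON)
        per_image.append(
            {
                "dsb_score": float(dsb.mean()),
                "mAP": float(prec.mean()),
                "mAR": float(rec.mean()),
                "mF1": float(f1.mean()),
            }
        )
    agg = {k: float(np.mean([d[k] for d in per_image])) for k in ("dsb_score", "mAP", "mAR", "mF1")}
    return ScoreReport(agg["dsb_score"], agg["mAP"], agg["mAR"], agg["mF1"], per_image)


# ---------------------------------------------------------------------------
# Error taxonomy
# ---------------------------------------------------------------------------


def _overlap_matrix(pred: InstanceSet, gt: InstanceSet) -> np.ndarray:
    """(n_gt, n_pred) pixel intersection counts."""
    if pred.shape != gt.shape:
        raise DimensionError(f"canvas mismatch: {pred.shape} vs {gt.shape}")
    gt_idx = [gt.ravelled(i) for i in range(len(gt))]
    pr_idx = [pred.ravelled(j) for j in range(len(pred))]
    m = np.zeros((len(gt), len(pred)), dtype=np.int64)
    for i, gi in enumerate(gt_idx):
        for j, pj in enumerate(pr_idx):
            m[i, j] = np.intersect1d(gi, pj, assume_unique=True).size
    return m


def _count_splits(cover: np.ndarray, areas: np.ndarray, matched: np.ndarray) -> tuple[int, int]:
    """Count split (resp. merge) events and uncovered objects.

    ``cover[i, j]``: pixels of object i covered by counterpart j; ``areas[i]``
    the object's own area (the overlap denominator); ``matched[i]`` whether
    object i already has a one-to-one IoU>0.5 partner.
    Returns (n_split_like, n_uncovered).
    """
    n_split = 0
    n_uncovered = 0
    for i in range(cover.shape[0]):
        frac = cover[i] / areas[i]
        if matched[i]:
            continue
        if (frac >= SPLIT_MERGE_MAJOR).sum() >= 2 or (frac >= SPLIT_MERGE_MINOR).sum() >= 3:
            n_split += 1
        elif (frac >= SPLIT_MERGE_MINOR).sum() == 0:
            n_uncovered += 1
    return n_split, n_uncovered


def error_taxonomy(pred: InstanceSet, gt: InstanceSet) -> ErrorCounts:
    """Classify disagreements into missed / falsely detected / split / merged.

    * missed: a GT object with no IoU>0.5 match and no prediction covering at
      least 15% of it.
    * false detection: a prediction with no IoU>0.5 match and no GT covering
      at least 15% of it.
    * split: a GT object without a single match, covered >=30% each by two
      predictions (>=15% each when three or more contribute).
    * merged: the same rule with the roles of GT and predictions swapped.

    Overlap fractions are always measured relative to the covered object's own
    area.
    """
    inter = _overlap_matrix(pred, gt)
    table = match_objects(pred, gt, thresholds=(0.5,))
    matched_gt = np.zeros(len(gt), dtype=bool)
    matched_pred = np.zeros(len(pred), dtype=bool)
    gt_pos = {lab: i for i, lab in enumerate(gt.labels)}
    pred_pos = {lab: j for j, lab in enumerate(pred.labels)}
    for glab, plab, iou_val in table.pairs:
        if iou_val > 0.5:
            matched_gt[gt_pos[glab]] = True
            matched_pred[pred_pos[plab]] = True
    gt_areas = gt.areas().astype(np.float64)
    pred_areas = pred.areas().astype(np.float64)
    split, missed = _count_splits(inter, gt_areas, matched_gt) if len(gt) else (0, 0)
    merged, false_det = _count_splits(inter.T, pred_areas, matched_pred) if len(pred) else (0, 0)
    return ErrorCounts(missed=missed, false_detected=false_det, split=split, merged=merged)


# ---------------------------------------------------------------------------
# Mask loss and accuracy
# ---------------------------------------------------------------------------

BCE_CLIP = 1e-12


def mask_bce_loss(pred_probs: np.ndarray, gt: np.ndarray) -> float:
    """Average binary cross-entropy over an m x m ROI mask.

    ``-(1/m^2) sum[y log yhat + (1-y) log(1-yhat)]`` with predictions clipped
    to [1e-12, 1-1e-12] so saturated values give a finite loss.
    """
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred_probs.shape != gt.shape:
        raise DimensionError(f"grid shapes differ: {pred_probs.shape} vs {gt.shape}")
    p = np.clip(pred_probs, BCE_CLIP, 1.0 - BCE_CLIP)
    loss = -(gt * np.log(p) + (1.0 - gt) * np.log(1.0 - p))
    return float(loss.mean())


def classification_accuracy(calls, truth) -> float:
    """Fraction of binary calls matching the truth."""
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.size == 0 or calls.shape != truth.shape:
        raise ValueError("calls and truth must be equal-length and non-empty")
    return float((calls == truth).mean())
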