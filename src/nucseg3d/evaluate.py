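"""Instance matching and segmentation metrics.

Predicted and ground-truth instances are paired by intersection over union
(IoU = TP / (TP + FP + FN) at the voxel level per pair). At a threshold tau,
true positives are one-to-one pairings with IoU strictly greater than tau,
found by an optimal assignment that maximizes the number of matched pairs
and, among such matchings, the total IoU — so no predicted instance can
claim a ground-truth object already assigned to another. From the counts,

    F1 = 2TP / (2TP + FP + FN),  precision = TP / (TP + FP),
    recall = TP / (TP + FN).

The F1 profile over IoU thresholds 0.1..0.9 (step 0.1) plus its mean is the
standard instance report; F1 without an IoU threshold equals the Dice score
on the semantic (boolean) masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchCounts",
    "F1Curve",
    "iou_matrix",
    "match_at_threshold",
    "precision_from_counts",
    "recall_from_counts",
    "f1_from_counts",
    "f1_curve",
    "semantic_dice",
    "find_best_threshold",
    "evaluation_report",
]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int
    iou_threshold: float
    matched_ious: tuple = ()


@dataclass
class F1Curve:
    thresholds: tuple
    f1: tuple
    precision: tuple
    recall: tuple
    mean_f1: float = field(init=False)

    def __post_init__(self):
        self.mean_f1 = float(np.mean(self.f1)) if self.f1 else 0.0


def _relabel(x):
    labels = np.unique(x)
    labels = labels[labels > 0]
    lut = np.zeros(int(x.max(initial=0)) + 1, dtype=np.int64)
    lut[labels] = np.arange(1, labels.size + 1)
    return lut[x], labels


def iou_matrix(pred: np.ndarray, gt: np.ndarray):
    """Pairwise IoU between all predicted and ground-truth instances.

    Returns ``(ious, pred_labels, gt_labels)`` with ``ious[i, j]`` the IoU of
    ``pred_labels[i]`` against ``gt_labels[j]``; background (0) is excluded.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p, pred_labels = _relabel(pred)
    g, gt_labels = _relabel(gt)
    np_, ng = pred_labels.size, gt_labels.size
    joint = p.ravel() * (ng + 1) + g.ravel()
    counts = np.bincount(joint, minlength=(np_ + 1) * (ng + 1)).reshape(np_ + 1, ng + 1)
    inter = counts[1:, 1:].astype(np.float64)
    area_p = counts[1:, :].sum(axis=1, keepdims=True)
    area_g = counts[:, 1:].sum(axis=0, keepdims=True)
    union = area_p + area_g - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        ious = np.where(union > 0, inter / union, 0.0)
    return ious, pred_labels, gt_labels


_BIG = 1e6  # dominates any achievable total IoU, so cardinality wins first


def match_at_threshold(ious: np.ndarray, tau: float) -> MatchCounts:
    """Optimal one-to-one matching of instance pairs with IoU > tau."""
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must be in [0, 1)")
    ious = np.atleast_2d(np.asarray(ious, dtype=np.float64))
    n_pred, n_gt = ious.shape
    if n_pred == 0 or n_gt == 0:
        return MatchCounts(tp=0, fp=n_pred, fn=n_gt, iou_threshold=tau)
    qualifies = ious > tau
    score = np.where(qualifies, _BIG + ious, 0.0)
    rows, cols = linear_sum_assignment(-score)
    matched = [(r, c) for r, c in zip(rows, cols) if qualifies[r, c]]
    tp = len(matched)
    return MatchCounts(
        tp=tp,
        fp=n_pred - tp,
        fn=n_gt - tp,
        iou_threshold=tau,
        matched_ious=tuple(float(ious[r, c]) for r, c in matched),
    )


def precision_from_counts(c: MatchCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else (1.0 if c.fn == 0 else 0.0)


def recall_from_counts(c: MatchCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else (1.0 if c.fp == 0 else 0.0)


def f1_from_counts(c: MatchCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN); when nothing is predicted and nothing is
    annotated the score is 1 by convention."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def f1_curve(pred: np.ndarray, gt: np.ndarray, thresholds=IOU_THRESHOLDS) -> F1Curve:
    """F1 (with precision/recall) at each IoU threshold, plus the mean F1."""
    ious, _, _ = iou_matrix(pred, gt)
    f1s, precs, recs = [], [], []
    for tau in thresholds:
        c = match_at_threshold(ious, float(tau))
        f1s.append(f1_from_counts(c))
        precs.append(precision_from_counts(c))
        recs.append(recall_from_counts(c))
    return F1Curve(tuple(float(t) for t in thresholds), tuple(f1s), tuple(precs), tuple(recs))


def semantic_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice score 2|a n b| / (|a| + |b|); two empty masks score 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 10))


def find_best_threshold(prob_label_pairs, grid=DEFAULT_THRESHOLD_GRID, class_index: int = 1) -> float:
    """Dice-maximizing probability threshold, averaged over image pairs.

    For each (probabilities, boolean labels) pair the grid threshold
    maximizing the Dice between ``p[class_index] > t`` and the labels is
    found (ties broken toward the lower threshold); the per-image optima are
    averaged into the fold threshold. The default grid spans 0.05..0.95,
    excluding the degenerate endpoints.
    """
    pairs = list(prob_label_pairs)
    if not pairs or not len(grid):
        raise ValueError("need at least one (probs, labels) pair and a non-empty grid")
    optima = []
    for probs, labels in pairs:
        probs = np.asarray(probs)
        fg = probs[class_index] if probs.ndim == 4 else probs
        labels = np.asarray(labels).astype(bool)
        best_t, best_d = None, -1.0
        for t in grid:
            d = semantic_dice(fg > t, labels)
            if d > best_d:  # strict: ties keep the earlier (lower) threshold
                best_t, best_d = float(t), d
        optima.append(best_t)
    return float(np.mean(optima))


def evaluation_report(pred: np.ndarray, gt: np.ndarray) -> pd.DataFrame:
    """One row per IoU threshold (F1/precision/recall) plus a summary row
    carrying the mean F1 and the semantic Dice."""
    curve = f1_curve(pred, gt)
    rows = [
        {"iou_threshold": t, "f1": f, "precision": p, "recall": r}
        for t, f, p, r in zip(curve.thresholds, curve.f1, curve.precision, curve.recall)
    ]
    rows.append(
        {
            "iou_threshold": "mean/dice",
            "f1": curve.mean_f1,
            "precision": float(np.mean(curve.precision)),
            "recall": float(np.mean(curve.recall)),
            "semantic_dice": semantic_dice(pred > 0, gt > 0),
        }
    )
    return pd.DataFrame(rows)
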