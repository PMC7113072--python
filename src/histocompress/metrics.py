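"""Performance metrics: pixel-level F1 and AUC, and matched detection F1.

Detection matching solves a maximum-cardinality, minimum-total-distance
one-to-one assignment between predicted and ground-truth centers, with
pairs admissible only within a distance *radius* — the standard way a
"correctly detected" cell is scored against annotated centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .errors import DimensionError, ParameterError, UndefinedMetricError

__all__ = ["DetectionMatch", "pixel_f1", "pixel_auc", "match_detections", "detection_f1"]


@dataclass(frozen=True)
class DetectionMatch:
    """Outcome of one-to-one center matching within a radius."""

    tp: int
    fp: int
    fn: int
    #: matched (pred_index, gt_index, distance_px) triples; len == tp
    pairs: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)


def pixel_f1(pred: np.ndarray, gt: np.ndarray) -> float:
    """F1 = 2TP / (2TP + FP + FN) over binary pixel masks.

    Two empty masks agree perfectly and score 1.0 (warned, since the image
    then carries no signal for the task).
    """
    pred = np.asarray(pred, bool)
    gt = np.asarray(gt, bool)
    if pred.shape != gt.shape:
        raise DimensionError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    if tp == fp == fn == 0:
        warnings.warn("both masks empty; F1 defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def pixel_auc(prob: np.ndarray, gt: np.ndarray) -> float:
    """Area under the ROC curve over pixels.

    Equals the Mann-Whitney statistic: the fraction of positive-negative
    pixel pairs ranked concordantly, with 0.5 credit per tie.
    """
    prob = np.asarray(prob, float).ravel()
    gt = np.asarray(gt, bool).ravel()
    if prob.shape != gt.shape:
        raise DimensionError(f"shape mismatch: {prob.shape} vs {gt.shape}")
    if gt.all() or not gt.any():
        raise UndefinedMetricError("pixel AUC needs both classes in the ground truth")
    return float(roc_auc_score(gt, prob))


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DimensionError(f"expected (n, 2) point array, got shape {pts.shape}")
    return pts


def match_detections(pred, gt, radius: float) -> DetectionMatch:
    """Optimally pair predicted and ground-truth centers within *radius* px.

    Among all one-to-one pairings using only pairs with distance <= radius,
    the match maximizes the number of pairs and, among those, minimizes the
    total distance. Unmatched predictions are false positives; unmatched
    ground truth, false negatives.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    pred = _as_points(pred)
    gt = _as_points(gt)
    if len(pred) == 0 or len(gt) == 0:
        return DetectionMatch(tp=0, fp=len(pred), fn=len(gt))
    dist = cdist(pred, gt)
    feasible = dist <= radius
    # a cost larger than any feasible total makes cardinality dominate distance
    big = radius * (dist.shape[0] + dist.shape[1] + 1) + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (int(r), int(c), float(dist[r, c]))
        for r, c in zip(rows, cols) if feasible[r, c]
    )
    tp = len(pairs)
    return DetectionMatch(tp=tp, fp=len(pred) - tp, fn=len(gt) - tp, pairs=pairs)


def detection_f1(match: DetectionMatch) -> float:
    """F1 over matched detections; a vacuously perfect match (no objects,
    no predictions) scores 1.0."""
    denom = 2 * match.tp + match.fp + match.fn
    if denom == 0:
        return 1.0
    return 2.0 * match.tp / denom
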