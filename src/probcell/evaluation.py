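"""Detection evaluation: optimal point matching and score computation.

Predictions are matched one-to-one to ground-truth annotations by minimizing
the total Euclidean distance of the assignment (Hungarian algorithm on the
rectangular distance matrix; the smaller set is fully assigned).  Pairs within
``t_match`` = 4 um (inclusive) are true positives; a pair farther apart counts
as one false positive (the prediction) and one false negative (the GT), as do
unmatched predictions and unmatched GT respectively.

Probability calibration is scored with the Brier score and the negative
log-likelihood over the union of GT coordinates (reference probability 1) and
false-positive predictions (reference probability 0); a missing counterpart
contributes probability 0.  Deterministic detectors are scored by assigning
probability 1 to every prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "MatchResult",
    "ScoreReport",
    "hungarian_match",
    "classify_detections",
    "detection_scores",
    "calibration_scores",
    "evaluate_detections",
]

DEFAULT_T_MATCH = 4.0
#: probability clamp so deterministic p in {0, 1} yields a finite NLL
NLL_EPS = 1e-12


@dataclass
class MatchResult:
    """One-to-one assignment between GT and predictions.

    ``pairs`` rows are ``(gt_index, pred_index, distance_um)``; indices not in
    any pair appear in ``unmatched_gt`` / ``unmatched_pred``.
    """

    pairs: np.ndarray
    unmatched_gt: np.ndarray
    unmatched_pred: np.ndarray
    n_gt: int
    n_pred: int


@dataclass
class ScoreReport:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    brier: float | None = None
    nll: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _coords(obj) -> np.ndarray:
    c = np.asarray(getattr(obj, "coords", obj), dtype=float)
    return c.reshape(0, 3) if c.size == 0 else np.atleast_2d(c)


def hungarian_match(gt, pred) -> MatchResult:
    """Optimal one-to-one matching minimizing total Euclidean distance.

    Accepts AnnotationSet/ProposalSet or bare ``(n, 3)`` arrays; either side
    may be empty.
    """
    g, p = _coords(gt), _coords(pred)
    if g.shape[0] == 0 or p.shape[0] == 0:
        return MatchResult(
            pairs=np.empty((0, 3)),
            unmatched_gt=np.arange(g.shape[0]),
            unmatched_pred=np.arange(p.shape[0]),
            n_gt=g.shape[0],
            n_pred=p.shape[0],
        )
    cost = cdist(g, p)
    rows, cols = linear_sum_assignment(cost)
    pairs = np.column_stack([rows, cols, cost[rows, cols]])
    unmatched_gt = np.setdiff1d(np.arange(g.shape[0]), rows)
    unmatched_pred = np.setdiff1d(np.arange(p.shape[0]), cols)
    return MatchResult(pairs, unmatched_gt, unmatched_pred, g.shape[0], p.shape[0])


def classify_detections(match: MatchResult, t_match: float = DEFAULT_T_MATCH):
    """Partition a match into (TP, FP, FN) counts at ``t_match`` (inclusive)."""
    if match.pairs.shape[0]:
        within = match.pairs[:, 2] <= t_match
        tp = int(within.sum())
        far = int((~within).sum())
    else:
        tp, far = 0, 0
    fp = far + len(match.unmatched_pred)
    fn = far + len(match.unmatched_gt)
    return tp, fp, fn


def detection_scores(tp: int, fp: int, fn: int):
    """Precision, recall, and F1 with the 0/0 := 0 convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def _calibration_terms(match: MatchResult, pred_probs, t_match: float):
    """Reference/predicted probability pairs over GT coordinates and FPs."""
    pred_probs = np.asarray(pred_probs, dtype=float)
    if pred_probs.shape[0] != match.n_pred:
        raise ValueError("one probability per prediction required")
    ref, est = [], []
    matched_gt_prob = np.zeros(match.n_gt)
    matched_within = np.zeros(match.n_pred, dtype=bool)
    for gi, pi, dist in match.pairs:
        gi, pi = int(gi), int(pi)
        if dist <= t_match:
            matched_gt_prob[gi] = pred_probs[pi]
            matched_within[pi] = True
    # every GT coordinate: reference probability 1
    for gi in range(match.n_gt):
        ref.append(1.0)
        est.append(matched_gt_prob[gi])
    # every FP prediction: reference probability 0
    for pi in range(match.n_pred):
        if not matched_within[pi]:
            ref.append(0.0)
            est.append(pred_probs[pi])
    return np.asarray(ref), np.asarray(est)


def calibration_scores(
    match: MatchResult,
    pred_probs,
    t_match: float = DEFAULT_T_MATCH,
):
    """Brier score and NLL of predicted probabilities against the match.

    Both are means over the union of GT coordinates and FP predictions.  The
    NLL uses the natural logarithm with probabilities clamped to
    ``[1e-12, 1 - 1e-12]``.
    """
    ref, est = _calibration_terms(match, pred_probs, t_match)
    if ref.size == 0:
        return 0.0, 0.0
    if ((est < 0) | (est > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    brier = float(((ref - est) ** 2).mean())
    q = np.clip(est, NLL_EPS, 1.0 - NLL_EPS)
    nll = float(-(ref * np.log(q) + (1.0 - ref) * np.log(1.0 - q)).mean())
    return brier, nll


def evaluate_detections(
    gt,
    pred,
    t_match: float = DEFAULT_T_MATCH,
    pred_probs=None,
) -> ScoreReport:
    """Full report: match, count, score; calibration if probabilities exist.

    If ``pred_probs`` is omitted, probabilities attached to ``pred`` are used;
    failing that the deterministic convention (p = 1 per prediction) applies
    for the calibration part.
    """
    match = hungarian_match(gt, pred)
    tp, fp, fn = classify_detections(match, t_match)
    precision, recall, f1 = detection_scores(tp, fp, fn)
    if pred_probs is None:
        pred_probs = getattr(pred, "probabilities", None)
    if pred_probs is None:
        pred_probs = np.ones(match.n_pred)
    brier, nll = calibration_scores(match, pred_probs, t_match)
    return ScoreReport(precision, recall, f1, tp, fp, fn, brier, nll)
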