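"""Classifier evaluation: ROC/AUC, DeLong comparison, decision curves,
calibration.

AUC is the trapezoidal area under the ROC curve (equivalently the
Mann-Whitney concordance probability).  The DeLong test compares two
correlated AUCs on the same cases via placement values (structural
components).  Decision-curve analysis reports the net benefit

    NB(pt) = TP/N - (FP/N) * pt / (1 - pt)

against the treat-all and treat-none policies across threshold
probabilities pt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.calibration import calibration_curve as _sk_calibration
from sklearn.metrics import brier_score_loss, confusion_matrix, roc_auc_score, roc_curve

__all__ = [
    "ModelEvaluation",
    "evaluate",
    "delong_test",
    "decision_curve",
    "calibration_curve",
]


@dataclass
class ModelEvaluation:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    brier: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    roc_points: Tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    threshold: float = 0.5
    flags: list = field(default_factory=list)


def evaluate(probs: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5) -> ModelEvaluation:
    """Discrimination and calibration metrics of predicted probabilities."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    flags = []
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined on a single-class test set")
    auc = float(roc_auc_score(labels, probs))
    fpr, tpr, _ = roc_curve(labels, probs)
    cm = confusion_matrix(labels, (probs >= threshold).astype(int), labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    return ModelEvaluation(
        auc=auc,
        accuracy=(tp + tn) / cm.sum(),
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        brier=float(brier_score_loss(labels, probs)),
        confusion=cm,
        roc_points=(fpr, tpr),
        threshold=threshold,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the V10 (per positive) and V01 (per negative) placement
    values of one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_test(scores_a, scores_b, labels) -> Tuple[float, float, float]:
    """Two-sided DeLong comparison of two correlated AUCs.

    Returns (auc_a, auc_b, p_value).  Identical score orderings give zero
    variance of the AUC difference; that degenerate case returns p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must share one length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

def decision_curve(
    probs: Sequence[float],
    labels: Sequence[int],
    thresholds: Optional[Sequence[float]] = None,
):
    """Net benefit of the model, treat-all and treat-none across thresholds.

    Returns a dict with 'threshold', 'net_benefit', 'treat_all',
    'treat_none' arrays.  Thresholds >= 1 are excluded.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray([t for t in np.asarray(thresholds, float) if 0 < t < 1])
    N = len(labels)
    prevalence = labels.mean()
    nb = np.empty(len(thresholds))
    ta = np.empty(len(thresholds))
    for i, pt in enumerate(thresholds):
        pred = probs >= pt
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        w = pt / (1.0 - pt)
        nb[i] = tp / N - (fp / N) * w
        ta[i] = prevalence - (1.0 - prevalence) * w
    return {
        "threshold": thresholds,
        "net_benefit": nb,
        "treat_all": ta,
        "treat_none": np.zeros(len(thresholds)),
        "prevalence": float(prevalence),
    }


def calibration_curve(
    probs: Sequence[float], labels: Sequence[int], n_bins: int = 10
):
    """Reliability diagram points plus the Brier score.

    Equal-width probability bins; empty bins are omitted.  Returns
    (mean_predicted, observed_fraction, brier).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    frac_pos, mean_pred = _sk_calibration(labels, probs, n_bins=n_bins,
                                          strategy="uniform")
    brier = float(np.mean((probs - labels) ** 2))
    return mean_pred, frac_pos, brier
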