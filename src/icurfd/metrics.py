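"""Evaluation suite: ROC/PRC curves, AUROC, partial AUROC, the interpolated
specificity-0.7 operating point, Brier score and Spearman rank agreement.

Accuracy and F1 at the operating point are computed from fractional
confusion-matrix entries implied by linear interpolation in ROC space
(``mode="interpolated"``, the default); ``mode="nearest"`` instead uses the
realised curve point closest to the requested specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import precision_recall_curve
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class RocCurve:
    """ROC points ordered by non-decreasing FPR, spanning (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class PrcCurve:
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray


@dataclass
class OperatingPoint:
    specificity: float
    sensitivity: float
    fpr: float


@dataclass
class MetricReport:
    """One scorer's metric suite at the stated operating point."""

    auroc: float
    pauroc: float
    accuracy: float
    f1: float
    specificity: float
    sensitivity: float
    brier: float

    def as_dict(self) -> dict[str, float]:
        return {
            "AUROC": self.auroc,
            "Accuracy": self.accuracy,
            "F1": self.f1,
            "Specificity": self.specificity,
            "pAUROC": self.pauroc,
            "Brier": self.brier,
            "Sensitivity": self.sensitivity,
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to trace a curve")


def roc_curve(scores, labels) -> RocCurve:
    """Threshold-sweep ROC with tied scores grouped at one threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def prc_curve(scores, labels) -> PrcCurve:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    precision, recall, thr = precision_recall_curve(labels, scores)
    return PrcCurve(recall=recall, precision=precision, thresholds=thr)


def auroc(scores, labels) -> float:
    """Trapezoidal area under the ROC (equals midrank concordance)."""
    c = roc_curve(scores, labels)
    return float(np.trapezoid(c.tpr, c.fpr))


def pauroc(roc: RocCurve, max_fpr: float = 0.3) -> float:
    """Trapezoidal ROC area over FPR in [0, max_fpr] (max value max_fpr)."""
    if not 0.0 < max_fpr <= 1.0:
        raise ValueError(f"max_fpr must lie in (0, 1], got {max_fpr}")
    fpr, tpr = roc.fpr, roc.tpr
    mask = fpr <= max_fpr
    xs, ys = fpr[mask], tpr[mask]
    if xs[-1] < max_fpr:  # boundary falls inside a horizontal segment
        xs = np.append(xs, max_fpr)
        ys = np.append(ys, float(np.interp(max_fpr, fpr, tpr)))
    return float(np.trapezoid(ys, xs))


def operating_point(roc: RocCurve, specificity: float = 0.7) -> OperatingPoint:
    """Linearly interpolate the ROC at FPR = 1 - specificity.

    At a vertical segment (duplicated FPR values) the upper envelope is
    taken, so an on-grid point returns its own TPR.
    """
    if not 0.0 <= specificity <= 1.0:
        raise ValueError("specificity must lie in [0, 1]")
    fpr_star = 1.0 - specificity
    # np.interp takes the *last* matching knot for tied x, i.e. the upper
    # envelope of the ROC step at fpr_star
    sens = float(np.interp(fpr_star, roc.fpr, roc.tpr))
    return OperatingPoint(specificity=specificity, sensitivity=sens, fpr=fpr_star)


def _nearest_point(roc: RocCurve, specificity: float) -> OperatingPoint:
    fpr_star = 1.0 - specificity
    i = int(np.argmin(np.abs(roc.fpr - fpr_star)))
    return OperatingPoint(
        specificity=1.0 - float(roc.fpr[i]),
        sensitivity=float(roc.tpr[i]),
        fpr=float(roc.fpr[i]),
    )


def brier(scores, labels) -> float:
    """Mean squared difference between probability scores and labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size == 0:
        raise ValueError("empty input")
    if np.any((scores < -1e-9) | (scores > 1 + 1e-9)):
        raise ValueError("scores must lie in [0, 1]")
    scores = np.clip(scores, 0.0, 1.0)  # absorb float round-off from weight sums
    return float(np.mean((scores - labels) ** 2))


def spearman_rank(ranking_a, ranking_b) -> float:
    """Spearman correlation with midrank ties, in [-1, 1]."""
    a = np.asarray(ranking_a, dtype=float)
    b = np.asarray(ranking_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rankings must have equal length")
    return float(spearmanr(a, b).statistic)


def compute_report(
    scores,
    labels,
    specificity: float = 0.7,
    max_fpr: float = 0.3,
    mode: str = "interpolated",
) -> MetricReport:
    """Full metric suite for one scorer on one labelled test set.

    Accuracy and F1 come from fractional confusion entries at the known
    class prevalence: with sensitivity s, specificity c and prevalence p,
    TP = s*p, FN = (1-s)*p, FP = (1-c)*(1-p), TN = c*(1-p).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    curve = roc_curve(scores, labels)
    if mode == "interpolated":
        op = operating_point(curve, specificity)
    elif mode == "nearest":
        op = _nearest_point(curve, specificity)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    prevalence = float(labels.mean())
    tp = op.sensitivity * prevalence
    fn = (1.0 - op.sensitivity) * prevalence
    fp = (1.0 - op.specificity) * (1.0 - prevalence)
    tn = op.specificity * (1.0 - prevalence)
    accuracy = tp + tn
    f1 = 2.0 * tp / (2.0 * tp + fp + fn) if (2.0 * tp + fp + fn) > 0 else 0.0
    return MetricReport(
        auroc=float(np.trapezoid(curve.tpr, curve.fpr)),
        pauroc=pauroc(curve, max_fpr),
        accuracy=float(accuracy),
        f1=float(f1),
        specificity=float(op.specificity),
        sensitivity=float(op.sensitivity),
        brier=brier(scores, labels),
    )
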