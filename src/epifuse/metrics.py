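"""Binary-classification evaluation statistics for epitope prediction.

Seven statistics over the 2x2 confusion matrix (class 1 = IFN-gamma
inducing = positive): sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy, Matthews correlation coefficient, precision TP/(TP+FP), F1, and
AUC.  AUC uses the rank (Mann-Whitney) estimator with half credit for
ties, which equals the trapezoidal area under the ROC curve.

Degenerate ratios (zero denominator) report 0 with a logged warning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """The four cells of the binary confusion matrix."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise ValueError("confusion matrix is empty")


@dataclass(frozen=True)
class MetricsReport:
    """The seven evaluation statistics; auc is None when no scores given."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    precision: float
    f1: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self) -> str:
        rows = [
            f"{name:<12s} {value:.4f}"
            for name, value in self.to_dict().items()
            if value is not None
        ]
        return "\n".join(rows)


def _validate_binary(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError(f"{what} must contain only 0/1")
    return values.astype(int)


def confusion(labels_true: Sequence[int], labels_pred: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate true vs predicted binary labels."""
    y = _validate_binary(np.asarray(labels_true), "labels_true")
    p = _validate_binary(np.asarray(labels_pred), "labels_pred")
    if y.shape != p.shape or y.size == 0:
        raise ValueError("labels_true and labels_pred must be equal-length, non-empty")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def rank_auc(scores: Sequence[float], labels_true: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    y = _validate_binary(np.asarray(labels_true), "labels_true")
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    counts: ConfusionCounts,
    scores: Sequence[float] | None = None,
    labels_true: Sequence[int] | None = None,
) -> MetricsReport:
    """Evaluate the confusion-matrix statistics, plus AUC when scores given."""
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    total = TP + TN + FP + FN
    sensitivity = _ratio(TP, TP + FN, "sensitivity")
    specificity = _ratio(TN, TN + FP, "specificity")
    accuracy = _ratio(TP + TN, total, "accuracy")
    precision = _ratio(TP, TP + FP, "precision")
    mcc_den = math.sqrt((TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    if mcc_den == 0:
        logger.warning("mcc undefined (zero denominator factor); reporting 0")
        mcc = 0.0
    else:
        mcc = (TP * TN - FP * FN) / mcc_den
    f1 = _ratio(2 * precision * sensitivity, precision + sensitivity, "f1")
    auc = None
    if scores is not None:
        if labels_true is None:
            raise ValueError("labels_true required alongside scores for AUC")
        auc = rank_auc(scores, labels_true)
    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        mcc=mcc,
        precision=precision,
        f1=f1,
        auc=auc,
    )


def roc_curve(
    scores: Sequence[float], labels_true: Sequence[int]
) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR), one threshold per distinct score, plus endpoints.

    The curve starts at (0, 0) ("predict nothing positive") and ends at
    (1, 1); its trapezoidal area equals :func:`rank_auc`.
    """
    y = _validate_binary(np.asarray(labels_true), "labels_true")
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each run of tied scores
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], int)
    cut = np.append(distinct, s_sorted.size - 1)
    points = [(0.0, 0.0)] + [
        (fp[i] / n_neg, tp[i] / n_pos) for i in cut
    ]
    return points


def roc_auc_trapezoid(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC point list."""
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))
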