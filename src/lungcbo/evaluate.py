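"""Confusion-matrix metrics, ROC/AUC, and error-histogram diagnostics.

Malignant is the positive class throughout (clinical convention: sensitivity
measures disease detection). Metrics with zero denominators are reported as
``None`` — explicit nulls, never silently coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

POSITIVE = "malignant"
NEGATIVE = "benign"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Scalar diagnostics; sensitivity and recall are one stored value."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    auc: float | None = None

    @property
    def recall(self) -> float | None:
        return self.sensitivity

    def as_dict(self, percentages: bool = False) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auc": self.auc,
        }
        if percentages:
            d = {k: (None if v is None else round(100.0 * v, 2)) for k, v in d.items()}
        return d


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN over benign/malignant label sequences."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    valid = {POSITIVE, NEGATIVE}
    unknown = (set(t) | set(p)) - valid
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    tp = sum(1 for a, b in zip(t, p) if a == POSITIVE and b == POSITIVE)
    tn = sum(1 for a, b in zip(t, p) if a == NEGATIVE and b == NEGATIVE)
    fp = sum(1 for a, b in zip(t, p) if a == NEGATIVE and b == POSITIVE)
    fn = sum(1 for a, b in zip(t, p) if a == POSITIVE and b == NEGATIVE)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """accuracy, sensitivity=TP/(TP+FN), specificity=TN/(TN+FP), precision=TP/(TP+FP)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return MetricsReport(
        accuracy=_ratio(c.TP + c.TN, c.total),
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.TN + c.FP),
        precision=_ratio(c.TP, c.TP + c.FP),
        auc=auc,
    )


def roc(scores, true_labels) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC; malignant predicted when score >= threshold.

    Returns (points, auc) with points an (m, 3) array of
    (threshold, fpr, tpr) rows covering every distinct score plus the (0,0)
    and (1,1) endpoints. The trapezoidal AUC equals the Mann-Whitney
    probability P(score_pos > score_neg) + 0.5 * P(tie).
    """
    y = np.array([1 if lab == POSITIVE else 0 for lab in true_labels])
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([thr, fpr, tpr]), auc


def error_histogram(
    predicted_probs,
    true_onehots,
    n_bins: int = 20,
    splits=None,
) -> dict[str, np.ndarray]:
    """Bin prediction errors (target - predicted positive-class probability).

    Errors lie in [-1, 1] and are binned into ``n_bins`` equal-width bins;
    counts are returned per split (a single "all" split when none given).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.asarray(predicted_probs, dtype=float)
    t = np.asarray(true_onehots, dtype=float)
    if p.ndim == 2:
        p = p[:, 1]
    if t.ndim == 2:
        t = t[:, 1]
    errors = t - p
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    if splits is None:
        splits = np.array(["all"] * errors.size)
    splits = np.asarray(splits)
    out = {}
    for name in np.unique(splits):
        counts, _ = np.histogram(errors[splits == name], bins=edges)
        out[str(name)] = counts
    return out
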