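"""Performance metrics: ROC curves, fold-averaged AUROC with 95 % CIs, and
the full multiclass confusion-matrix suite (accuracy, macro sensitivity /
specificity / precision / F1, Matthews correlation, Cohen's kappa).

The confusion-matrix metrics are computed directly from a count matrix so
that a published matrix can be re-analysed without access to the underlying
predictions.  Conventions: macro averages are unweighted class means; a
class with a zero marginal contributes 0 to the macro average for the
affected metric; multiclass MCC uses the covariance form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "RocCurve",
    "AverageAuroc",
    "ConfusionMetrics",
    "roc_and_auroc",
    "multiclass_auroc",
    "average_auroc",
    "confusion_metrics",
]


@dataclass
class RocCurve:
    """Threshold-sweep ROC curve with its area.

    The AUROC equals the Mann-Whitney U statistic normalized by n+·n-
    (tied scores counted 1/2), i.e. the probability that a random positive
    outranks a random negative.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float

    def to_frame(self):
        """Delimited-text-ready table of the curve points."""
        import pandas as pd

        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def roc_and_auroc(predicted_scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and area for binary labels and continuous scores."""
    y = np.asarray(labels)
    s = np.asarray(predicted_scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to form a ROC curve")
    fpr, tpr, thr = _skm.roc_curve(y, s)
    auroc = float(_skm.auc(fpr, tpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auroc=auroc)


def multiclass_auroc(
    class_scores: np.ndarray, labels: Sequence, classes: Sequence | None = None
) -> float:
    """Macro-averaged one-vs-rest AUROC.

    `class_scores` has one column per class (column order given by
    `classes`, or the sorted unique labels).  Every class must appear in
    `labels`.
    """
    y = np.asarray(labels)
    scores = np.asarray(class_scores, dtype=float)
    classes = list(classes) if classes is not None else sorted(np.unique(y).tolist())
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("class_scores must have one column per class")
    present = set(np.unique(y).tolist())
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes absent from labels: {missing}")
    # unweighted mean of the per-class one-vs-rest areas; the class-c score
    # column ranks class c against the rest, so no normalization is needed
    per_class = [
        _skm.roc_auc_score((y == c).astype(int), scores[:, i])
        for i, c in enumerate(classes)
    ]
    return float(np.mean(per_class))


@dataclass
class AverageAuroc:
    """Fold-level metric values summarized by mean and 95 % CI."""

    values: list[float]
    mean: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def average_auroc(
    fold_values: Sequence[float], level: float = 0.95, method: str = "percentile"
) -> AverageAuroc:
    """Mean and confidence interval across fold-level metric values.

    The default interval is the percentile interval of the fold values; a
    normal approximation (mean ± z·sd/√n) is available via
    ``method="normal"``.
    """
    v = np.asarray(fold_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two fold values")
    mean = float(v.mean())
    alpha = (1.0 - level) / 2.0
    if method == "percentile":
        lo, hi = np.percentile(v, [100 * alpha, 100 * (1 - alpha)])
    elif method == "normal":
        from scipy import stats

        z = stats.norm.ppf(1 - alpha)
        half = z * v.std(ddof=1) / np.sqrt(v.size)
        lo, hi = mean - half, mean + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return AverageAuroc(
        values=v.tolist(), mean=mean, ci_low=float(lo), ci_high=float(hi), level=level
    )


@dataclass
class ConfusionMetrics:
    """Complete metric suite derived from a class × class count matrix."""

    matrix: np.ndarray
    classes: list[str]
    per_class_tpr: np.ndarray
    per_class_ppv: np.ndarray
    per_class_specificity: np.ndarray
    accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    macro_precision: float
    macro_f1: float
    mcc: float
    kappa: float

    def as_dict(self) -> dict:
        return {
            "classes": self.classes,
            "matrix": self.matrix.tolist(),
            "per_class_tpr": self.per_class_tpr.tolist(),
            "per_class_ppv": self.per_class_ppv.tolist(),
            "per_class_specificity": self.per_class_specificity.tolist(),
            "accuracy": self.accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
            "kappa": self.kappa,
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def confusion_metrics(
    matrix: Sequence[Sequence[float]], classes: Sequence[str] | None = None
) -> ConfusionMetrics:
    """All reported metrics from a confusion matrix (rows = true class,
    columns = predicted class).

    Per-class sensitivity (TPR) is diag/row-sum and precision (PPV) is
    diag/col-sum; specificity is TN/(TN+FP) per class.  Macro metrics are
    unweighted means across classes.  Cohen's kappa uses the expected
    agreement from row/column marginals; MCC uses the multiclass
    covariance form.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any() or m.sum() <= 0:
        raise ValueError("confusion matrix must be non-negative with positive total")
    k = m.shape[0]
    names = [str(c) for c in (classes if classes is not None else range(k))]
    if len(names) != k:
        raise ValueError("number of class names must match the matrix size")

    n = m.sum()
    diag = np.diag(m)
    row = m.sum(axis=1)  # true-class totals
    col = m.sum(axis=0)  # predicted-class totals

    tpr = _safe_div(diag, row)
    ppv = _safe_div(diag, col)
    fp = col - diag
    tn = n - row - col + diag
    spec = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * tpr * ppv, tpr + ppv)

    accuracy = float(diag.sum() / n)
    pe = float(np.dot(row, col) / n**2)
    kappa = float((accuracy - pe) / (1 - pe)) if pe < 1 else 1.0

    # multiclass MCC, covariance form
    num = diag.sum() * n - float(np.dot(row, col))
    den = np.sqrt(n**2 - float(np.dot(col, col))) * np.sqrt(n**2 - float(np.dot(row, row)))
    mcc = float(num / den) if den > 0 else 0.0

    return ConfusionMetrics(
        matrix=m,
        classes=names,
        per_class_tpr=tpr,
        per_class_ppv=ppv,
        per_class_specificity=spec,
        accuracy=accuracy,
        macro_sensitivity=float(tpr.mean()),
        macro_specificity=float(spec.mean()),
        macro_precision=float(ppv.mean()),
        macro_f1=float(f1.mean()),
        mcc=mcc,
        kappa=kappa,
    )
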