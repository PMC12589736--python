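"""Confusion-matrix metrics, one-vs-rest ROC AUC, and paired model comparison.

Per-class metrics use one-vs-rest counts: with TP/FN/FP/TN derived from the
confusion matrix for each class,

    sensitivity = TP/(TP+FN)·100        precision  = TP/(TP+FP)·100
    specificity = TN/(TN+FP)·100        accuracy   = (TP+TN)/total·100
    F1          = 2·P·S/(P+S)

Macro values are unweighted arithmetic means over classes; AUC is the
trapezoidal one-vs-rest ROC area (equivalently the tie-corrected rank
statistic). A metric with a zero denominator is reported as None (flagged
undefined), never silently as 0.

Two models sharing a test split are compared with a one-sided paired t-test
over their per-class F1 values (H1: model a scores higher), df = n−1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ComparisonResult",
    "confusion_matrix",
    "per_class_metrics",
    "f1_score",
    "roc_auc",
    "macro_report",
    "paired_f1_ttest",
]


@dataclass
class ConfusionMatrix:
    """classes × classes counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls) -> Dict[str, int]:
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"tp": tp, "fn": fn, "fp": fp, "tn": tn}


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     classes: Sequence) -> ConfusionMatrix:
    classes = list(classes)
    known = set(classes)
    for v in list(y_true) + list(y_pred):
        if v not in known:
            raise ValueError(f"label {v!r} not in class order {classes}")
    counts = _sk_confusion(list(y_true), list(y_pred), labels=classes)
    return ConfusionMatrix(counts=counts, classes=classes)


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def per_class_metrics(cm: ConfusionMatrix, cls) -> Dict[str, Optional[float]]:
    """One-vs-rest sensitivity/accuracy/precision/specificity (percent) for a class."""
    c = cm.one_vs_rest(cls)
    tp, fn, fp, tn = c["tp"], c["fn"], c["fp"], c["tn"]
    sens = _pct(tp, tp + fn)
    prec = _pct(tp, tp + fp)
    return {
        **c,
        "sensitivity": sens,
        "accuracy": _pct(tn + tp, cm.total),
        "precision": prec,
        "specificity": _pct(tn, tn + fp),
        "f1": None if sens is None or prec is None else f1_score(prec, sens),
    }


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (both in percent)."""
    if precision < 0 or sensitivity < 0:
        raise ValueError("precision and sensitivity must be >= 0")
    if precision == 0 and sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def roc_auc(y_true_binary: Sequence, scores: Sequence) -> float:
    """Trapezoidal ROC area for one-vs-rest truth vs continuous scores."""
    y = np.asarray(y_true_binary, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC undefined: only one class present in truth")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics, all as percentages."""

    classes: list
    per_class: dict                     # class -> metric dict
    macro: dict                         # metric -> macro mean
    overall_accuracy: float             # top-1 multiclass accuracy, percent

    def rounded(self, decimals_class: int = 1, decimals_macro: int = 2) -> dict:
        def _round(v, nd):
            return None if v is None else round(v, nd)
        return {
            "per_class": {c: {k: _round(v, decimals_class)
                              for k, v in m.items() if not isinstance(v, int)}
                          for c, m in self.per_class.items()},
            "macro": {k: _round(v, decimals_macro) for k, v in self.macro.items()},
            "overall_accuracy": round(self.overall_accuracy, decimals_macro),
        }


def macro_report(cm: ConfusionMatrix, scores: Optional[np.ndarray] = None,
                 y_true: Optional[Sequence] = None) -> MetricsReport:
    """Per-class one-vs-rest metrics plus their arithmetic macro means.

    ``scores`` (samples × classes, column order = cm.classes) and ``y_true``
    enable the per-class ROC AUC; without them AUC is reported as None.
    """
    per_class = {}
    for i, cls in enumerate(cm.classes):
        m = per_class_metrics(cm, cls)
        if scores is not None and y_true is not None:
            binary = (np.asarray(y_true) == cls).astype(int)
            m["auc"] = 100.0 * roc_auc(binary, np.asarray(scores)[:, i])
        else:
            m["auc"] = None
        per_class[cls] = m
    macro = {}
    for key in ("auc", "sensitivity", "accuracy", "precision", "specificity", "f1"):
        vals = [per_class[c][key] for c in cm.classes]
        macro[key] = None if any(v is None for v in vals) else float(np.mean(vals))
    overall = 100.0 * np.trace(cm.counts) / cm.total
    return MetricsReport(classes=list(cm.classes), per_class=per_class,
                         macro=macro, overall_accuracy=float(overall))


@dataclass
class ComparisonResult:
    mean_difference: float      # Δ, percentage points (a − b)
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significant: bool           # at alpha = 0.05, one-sided
    zero_variance: bool = False


def paired_f1_ttest(f1_a: Sequence[float], f1_b: Sequence[float],
                    alpha: float = 0.05) -> ComparisonResult:
    """One-sided paired t-test on per-class F1 values (H1: a > b).

    t = Δ / (sd(a−b)/√n) with the n−1 sample standard deviation, df = n−1.
    Zero-variance differences yield t = +∞ (p → 0) when Δ > 0, −∞ when
    Δ < 0, and a flagged no-difference result when Δ = 0.
    """
    a = np.asarray(f1_a, dtype=float)
    b = np.asarray(f1_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    n = len(d)
    delta = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if delta == 0.0:
            return ComparisonResult(mean_difference=0.0, t_statistic=0.0,
                                    degrees_of_freedom=df, p_value=1.0,
                                    significant=False, zero_variance=True)
        t = np.inf if delta > 0 else -np.inf
        return ComparisonResult(mean_difference=delta, t_statistic=float(t),
                                degrees_of_freedom=df,
                                p_value=0.0 if delta > 0 else 1.0,
                                significant=delta > 0, zero_variance=True)
    t = delta / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df))
    return ComparisonResult(mean_difference=delta, t_statistic=float(t),
                            degrees_of_freedom=df, p_value=p,
                            significant=p < alpha)
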