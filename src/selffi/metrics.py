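"""Multi-label evaluation: ROC/AUC, confusion-matrix metrics, per-class report.

The ROC curve is built from every distinct score threshold in descending
order (tied scores collapse to one threshold), and the AUC is its trapezoidal
area — equivalently the Mann–Whitney concordance statistic with ties counted
half.  Accuracy, precision, recall and F1 are the usual confusion-count
ratios at a fixed binarization threshold.  For the six-disease multi-label
task the summary "accuracy" is the unweighted mean of per-class binary
accuracies (not subset accuracy), and all macro numbers are unweighted means
over classes; classes whose AUC is undefined (a single label value in the
evaluation set) are flagged and excluded from the macro with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RocCurve:
    """Ordered (FPR, TPR) points from (0,0) to (1,1), both non-decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        f, t = np.asarray(self.fpr), np.asarray(self.tpr)
        if f.shape != t.shape or f.ndim != 1 or len(f) < 2:
            raise ValueError("a ROC curve needs matching 1-D fpr/tpr arrays")
        for arr, name in ((f, "fpr"), (t, "tpr")):
            if np.any(np.diff(arr) < 0) or arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} must be non-decreasing within [0, 1]")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC points at every distinct score threshold, descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1 - y)
    # keep only the last index of each tied-score block
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp_cum[distinct] / n_pos]
    fpr = np.r_[0.0, fp_cum[distinct] / n_neg]
    return RocCurve(fpr=fpr, tpr=tpr)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area: ½ Σ (xᵢ₊₁ − xᵢ)(yᵢ + yᵢ₊₁)."""
    x, y = np.asarray(curve.fpr), np.asarray(curve.tpr)
    return float(0.5 * np.sum((x[1:] - x[:-1]) * (y[1:] + y[:-1])))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    return auc_trapezoid(roc_curve(scores, labels))


def confusion(scores: np.ndarray, labels: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    """Tally confusion counts with prediction = (score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp + c.tn, c.n, "accuracy")


def precision(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn, "recall")


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        warnings.warn("F1 undefined (precision + recall = 0); reporting 0", stacklevel=2)
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass(frozen=True)
class MetricReport:
    """Per-class and macro metrics, all on the 0–1 scale."""

    per_class: pd.DataFrame       # index: class; columns: auc, accuracy, f1, precision, recall
    macro: dict[str, float]
    skipped_auc_classes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="index"),
            "macro": self.macro,
            "skipped_auc_classes": list(self.skipped_auc_classes),
        }


def report(score_table: pd.DataFrame, threshold: float = 0.5) -> MetricReport:
    """Evaluate a long-format score table (image_id, class, probability, label).

    Emits per-class AUC/accuracy/F1/precision/recall plus unweighted macro
    means.  Classes with only one label value present have no AUC; they are
    excluded from the macro AUC (with a warning) but still contribute their
    threshold-based metrics.
    """
    required = {"class", "probability", "label"}
    if score_table is None or len(score_table) == 0:
        raise ValueError("empty score table")
    if not required.issubset(score_table.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    rows = {}
    skipped = []
    for cls, grp in score_table.groupby("class", sort=True):
        scores = grp["probability"].to_numpy(dtype=float)
        labels = grp["label"].to_numpy(dtype=int)
        c = confusion(scores, labels, threshold)
        try:
            cls_auc: Optional[float] = auc(scores, labels)
        except ValueError:
            cls_auc = np.nan
            skipped.append(str(cls))
            warnings.warn(f"AUC undefined for class {cls!r}; excluded from macro AUC")
        rows[cls] = {
            "auc": cls_auc,
            "accuracy": accuracy(c),
            "f1": f1(c),
            "precision": precision(c),
            "recall": recall(c),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    if per_class["auc"].isna().all():
        raise ValueError("AUC undefined for every class (single-label table)")
    macro = {
        name: float(per_class[name].mean(skipna=(name == "auc")))
        for name in ("auc", "accuracy", "f1", "precision", "recall")
    }
    return MetricReport(per_class=per_class, macro=macro,
                        skipped_auc_classes=tuple(skipped))
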