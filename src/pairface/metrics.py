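"""Threshold metrics, ROC/AUC, best-F1 point and per-complex aggregation.

All prediction scores are real numbers in [0, 1]; a class prediction at a
threshold t calls a score positive iff score >= t.  The AUC is tie-aware
(ties count 1/2, so a constant predictor scores exactly 0.5) and equals the
normalised Mann-Whitney statistic.  In the leave-one-out protocol every
metric is computed per held-out complex and averaged unweighted over
complexes; model comparisons use the paired two-sided t-test over the
per-complex values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts", "RocCurve", "confusion_at", "metrics", "roc_auc",
    "best_f1_point", "aggregate_per_complex", "paired_model_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    """ROC points (recall vs 1-specificity) over the full threshold sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_inputs(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError(f"scores ({scores.shape}) and labels ({labels.shape}) differ")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with prediction positive iff score >= threshold."""
    scores, labels = _check_inputs(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict:
    """Recall/sensitivity, precision, specificity and F1 from counts.

    Ratios with a zero denominator come back as NaN; F1 is 0 when both
    precision and recall are 0 (or undefined).
    """
    def ratio(num, den):
        return num / den if den > 0 else np.nan

    recall = ratio(counts.tp, counts.tp + counts.fn)
    precision = ratio(counts.tp, counts.tp + counts.fp)
    specificity = ratio(counts.tn, counts.tn + counts.fp)
    if np.isnan(recall) or np.isnan(precision) or (precision + recall) == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"recall": recall, "precision": precision,
            "specificity": specificity, "f1": f1}


def roc_auc(scores, labels) -> RocCurve:
    """Tie-aware ROC curve and AUC (rank statistic, trapezoidal area)."""
    scores, labels = _check_inputs(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(roc_auc_score(labels, scores)))


def best_f1_point(scores, labels) -> dict:
    """Operating point maximising F1 over all distinct score thresholds.

    Ties in F1 resolve to the lowest threshold.  The sweep includes a
    threshold at or below the minimum score (everything predicted positive).
    """
    scores, labels = _check_inputs(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("best-F1 undefined: labels contain a single class")
    candidates = np.unique(scores)
    best = None
    for t in candidates:  # ascending, so '>' keeps the lowest-threshold winner
        m = metrics(confusion_at(scores, labels, t))
        if best is None or m["f1"] > best["f1"] + 1e-15:
            best = {"threshold": float(t), **m}
    return best


def aggregate_per_complex(per_complex_values) -> float:
    """Unweighted mean of a per-complex metric over leave-one-out cycles."""
    values = np.asarray(list(per_complex_values), dtype=float)
    if values.size == 0:
        raise ValueError("no per-complex values to aggregate")
    return float(values.mean())


def paired_model_test(values_a, values_b) -> dict:
    """Two-sided paired t-test between per-complex metric lists.

    Returns ``{"t", "p", "degenerate"}``; a zero-variance difference vector
    is flagged degenerate (p is NaN unless the lists are identical, in which
    case t=0, p=1).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length lists with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return {"t": 0.0, "p": 1.0, "degenerate": True}
        return {"t": np.inf if d.mean() > 0 else -np.inf, "p": np.nan,
                "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "degenerate": False}


def per_complex_report(rows) -> pd.DataFrame:
    """Assemble per-complex metric rows into the standard report layout."""
    return pd.DataFrame(
        rows,
        columns=["complex_id", "n_pairs", "n_pos", "auc", "best_f1",
                 "precision", "recall"],
    )
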