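"""ROC/AUC machinery, confusion metrics and single-marker baselines.

AUC is the rank-based (Mann-Whitney) statistic with mid-ranks for ties —
the probability that a random positive outranks a random negative. Marker
baselines mirror threshold-based single-variable classification: the AUC of
one feature column with an auto-chosen orientation and a seeded percentile
bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCCurve",
    "MarkerBaseline",
    "auc",
    "roc_points",
    "build_roc_curve",
    "confusion_metrics",
    "marker_baseline",
]


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if self.fpr[0] != 0 or self.fpr[-1] != 1 or self.tpr[0] != 0 or self.tpr[-1] != 1:
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if np.any(np.diff(self.fpr) < 0):
            raise ValueError("FPR must be non-decreasing")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class MarkerBaseline:
    marker: str
    auc: float
    ci_low: float
    ci_high: float
    higher_is_positive: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("bootstrap CI must contain the point AUC")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with mid-ranks; higher score = positive class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # mid-ranks for ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points from (0,0) to (1,1)."""
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return fpr, tpr


def build_roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    fpr, tpr = roc_points(scores, labels)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc(scores, labels))


def confusion_metrics(pred: np.ndarray, labels: np.ndarray) -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy from binary inputs.

    Ratios with a zero denominator are returned as NaN and listed under
    ``undefined`` rather than silently zeroed.
    """
    pred = np.asarray(pred).astype(int)
    labels = np.asarray(labels).astype(int)
    if pred.shape != labels.shape:
        raise ValueError("pred and labels must have the same shape")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(labels)) <= {0, 1}):
        raise ValueError("inputs must be binary")
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    out = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / pred.size,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }
    out["undefined"] = [k for k in ("sensitivity", "specificity", "ppv", "npv") if np.isnan(out[k])]
    return out


def marker_baseline(
    values: np.ndarray,
    labels: np.ndarray,
    marker: str = "marker",
    n_boot: int = 2000,
    seed: int = 0,
) -> MarkerBaseline:
    """Single-marker threshold baseline: oriented AUC with a percentile
    bootstrap 95% CI over ``n_boot`` seeded resamples.

    Orientation is flipped when the raw AUC is below 0.5 so the reported AUC
    is always >= 0.5 (markers where positives run *lower* are used inverted);
    the flag records the chosen orientation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(values).size == 1:
        warnings.warn(f"marker {marker!r} is constant; AUC degenerate at 0.5")
        return MarkerBaseline(marker=marker, auc=0.5, ci_low=0.5, ci_high=0.5, higher_is_positive=True)
    raw = auc(values, labels)
    higher = raw >= 0.5
    point = raw if higher else 1.0 - raw
    oriented = values if higher else -values

    rng = np.random.default_rng(seed)
    n = values.size
    boots = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.min() == lab.max():
            continue  # degenerate resample
        boots[kept] = auc(oriented[idx], lab)
        kept += 1
    if kept == 0:
        raise ValueError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(boots[:kept], [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return MarkerBaseline(
        marker=marker, auc=point, ci_low=float(lo), ci_high=float(hi), higher_is_positive=bool(higher)
    )
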