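"""Binary-classification metrics for residue-level binding prediction.

All threshold metrics derive from the 2×2 confusion matrix at a fixed
probability threshold (0.5 throughout the published experiments):

    PREC = TP/(TP+FP)        SN = TP/(TP+FN)         SP = TN/(TN+FP)
    F1 = 2TP/(2TP+FP+FN)     BACC = (SN+SP)/2        ACC = (TP+TN)/N
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

ROC AUC is computed by trapezoidal integration over all unique score
thresholds; AUPR uses step-wise interpolation of precision (no linear
interpolation), the convention appropriate under heavy class imbalance.
Ratios with zero denominators report 0 by convention; AUC/AUPR are NaN with a
warning when only one class is present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    bacc: float
    acc: float
    prec: float
    f1: float
    mcc: float
    auc: float
    aupr: float

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "SN": self.sn, "SP": self.sp, "BACC": self.bacc, "ACC": self.acc,
            "PREC": self.prec, "F1": self.f1, "MCC": self.mcc,
            "AUC": self.auc, "AUPR": self.aupr,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def confusion_counts(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with prediction = probability ≥ threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = p >= threshold
    tp = int(np.count_nonzero(pred & (y == 1)))
    fp = int(np.count_nonzero(pred & (y == 0)))
    tn = int(np.count_nonzero(~pred & (y == 0)))
    fn = int(np.count_nonzero(~pred & (y == 1)))
    return tp, fp, tn, fn


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve over all unique thresholds."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class labels: AUC undefined")
        return math.nan
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    distinct = np.r_[np.flatnonzero(np.diff(p_sorted)), len(p_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def average_precision(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve with step-wise precision."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or n_pos == len(y):
        warnings.warn("single-class labels: AUPR undefined")
        return math.nan
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    distinct = np.r_[np.flatnonzero(np.diff(p_sorted)), len(p_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = (distinct + 1) - tps
    precision = tps / (tps + fps)
    recall = tps / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def evaluate(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full metric report at the given class-discriminating threshold."""
    tp, fp, tn, fn = confusion_counts(probabilities, labels, threshold)
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, math.sqrt(denom)) if denom else 0.0
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sn=sn, sp=sp, bacc=(sn + sp) / 2,
        acc=_safe_div(tp + tn, tp + tn + fp + fn),
        prec=_safe_div(tp, tp + fp),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
        mcc=mcc,
        auc=roc_auc(probabilities, labels),
        aupr=average_precision(probabilities, labels),
    )
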