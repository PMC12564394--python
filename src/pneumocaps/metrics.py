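"""Binary diagnostic metrics: confusion matrix, the eight scalar measures
(accuracy, sensitivity, specificity, PPV, NPV, FPR, FNR, F1, MCC) and
ROC / precision-recall areas.

The positive class is pneumonia throughout.  Scalar metrics are computed
from their closed forms; any zero denominator yields NaN with the metric
name listed in ``MetricsReport.undefined`` — never a silent zero.  ROC AUC
uses trapezoidal integration over all thresholds (equivalently, pairwise
concordance with ties counted 1/2); PR AUC is the average precision over
the descending-score sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_array(self) -> np.ndarray:
        """Rows true (neg, pos), columns predicted (neg, pos)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


@dataclass
class MetricsReport:
    accuracy: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    fpr: float = math.nan
    fnr: float = math.nan
    f1: float = math.nan
    mcc: float = math.nan
    roc_auc: float = math.nan
    pr_auc: float = math.nan
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "accuracy", "sensitivity", "specificity", "ppv", "npv",
            "fpr", "fnr", "f1", "mcc", "roc_auc", "pr_auc")}
        d["undefined"] = list(self.undefined)
        return d


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    """Cross-tabulate binary labels (1 = pneumonia)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if not set(np.unique(y_true)) <= {0, 1} or not set(np.unique(y_pred)) <= {0, 1}:
        raise ValueError("labels must be binary (0 = normal, 1 = pneumonia)")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All scalar metrics of a confusion matrix.

    accuracy = (TP+TN)/total; sensitivity = TP/(TP+FN); specificity =
    TN/(TN+FP); PPV = TP/(TP+FP); NPV = TN/(TN+FN); FPR = FP/(FP+TN);
    FNR = FN/(FN+TP); F1 = 2*PPV*Rec/(PPV+Rec) = 2TP/(2TP+FP+FN);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    und: list[str] = []
    rep = MetricsReport(undefined=und)
    rep.accuracy = (tp + tn) / cm.total
    rep.sensitivity = _ratio(tp, tp + fn, "sensitivity", und)
    rep.specificity = _ratio(tn, tn + fp, "specificity", und)
    rep.ppv = _ratio(tp, tp + fp, "ppv", und)
    rep.npv = _ratio(tn, tn + fn, "npv", und)
    rep.fpr = _ratio(fp, fp + tn, "fpr", und)
    rep.fnr = _ratio(fn, fn + tp, "fnr", und)
    rep.f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", und)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        und.append("mcc")
    else:
        rep.mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return rep


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve (ties get half credit)."""
    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def pr_auc(y_true, scores) -> float:
    """Average precision: sum of (R_i - R_{i-1}) * P_i over the
    descending-score sweep."""
    y_true = np.asarray(y_true).astype(int)
    if y_true.sum() == 0:
        raise ValueError("average precision needs at least one positive sample")
    return float(average_precision_score(y_true, np.asarray(scores, dtype=float)))


def metrics_report(y_true, scores, y_pred) -> MetricsReport:
    """Scalar metrics from hard labels plus both curve areas from scores."""
    rep = compute_metrics(confusion_from_predictions(y_true, y_pred))
    rep.roc_auc = roc_auc(y_true, scores)
    rep.pr_auc = pr_auc(y_true, scores)
    return rep


def confusion_from_summary(total: int, fp: int, fn: int, sensitivity: float) -> ConfusionMatrix:
    """Reconstruct a confusion matrix from reported summary statistics.

    Given the evaluated-set size, the false-positive and false-negative
    counts and the sensitivity TP/(TP+FN), solve for the integer TP
    (rounding the implied real solution) and take TN as the remainder.
    Useful when a study reports these four quantities but not the matrix.
    """
    if not 0 < sensitivity < 1:
        raise ValueError("sensitivity must be in (0, 1) for the reconstruction")
    tp = int(round(sensitivity * fn / (1.0 - sensitivity)))
    tn = total - tp - fp - fn
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
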