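"""Classification and regression performance metrics.

Confusion-derived rates, Matthews correlation, ROC and precision-
recall curves with their areas, and Pearson/RMSE for regression.
auROC uses the Mann-Whitney tie convention (ties earn half credit);
auPR uses step-wise interpolation (no linear segments between
precision-recall points), the conservative standard.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _safe_div(num: float, den: float, default: float = 0.0) -> float:
    return num / den if den != 0 else default


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Threshold scores at >= threshold and derive the standard metrics.

    Degenerate denominators follow the total-report convention:
    precision/recall/F1 of an empty class are 0 and MCC of a degenerate
    table is 0 (flagged via the 'degenerate' key).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    counts = ConfusionCounts(tp, fp, tn, fn)

    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    degenerate = mcc_den == 0 or (tp + fp) == 0 or (tp + fn) == 0

    report = {
        "accuracy": _safe_div(tp + tn, counts.total),
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "mcc": mcc,
        "degenerate": bool(degenerate),
    }
    if len(np.unique(labels)) == 2:
        auroc, aupr, _, _ = curves(scores, labels)
        report["auroc"] = auroc
        report["aupr"] = aupr
    else:
        warnings.warn("only one class present; auROC/auPR undefined")
        report["auroc"] = None
        report["aupr"] = None
    return counts, report


def auroc_concordance(scores, labels) -> float:
    """auROC as P(random positive outranks random negative), ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def curves(scores, labels):
    """ROC and PR point tables with their areas, by threshold sweep.

    Thresholds are the unique score values in descending order; each
    threshold classifies rows with score >= t as positive.  Returns
    (auroc, aupr, roc_frame, pr_frame).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    cum_fp = np.cumsum(1 - sorted_labels)
    # indices of the last row of each tied score block
    block_end = np.nonzero(np.diff(sorted_scores, append=-np.inf) != 0)[0]
    tpr = np.concatenate([[0.0], cum_tp[block_end] / n_pos])
    fpr = np.concatenate([[0.0], cum_fp[block_end] / n_neg])
    auroc = float(np.trapezoid(tpr, fpr))

    tp_b = cum_tp[block_end]
    fp_b = cum_fp[block_end]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    # step-wise area: precision at each achieved recall times the recall gain
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    aupr = float(np.sum(precision * (recall - recall_prev)))

    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    pr = pd.DataFrame({"recall": recall, "precision": precision})
    return auroc, aupr, roc, pr


def regression_metrics(predicted, observed) -> dict:
    """Pearson correlation and RMSE between predictions and observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed) or len(predicted) < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    if np.std(predicted) == 0 or np.std(observed) == 0:
        warnings.warn("zero variance; Pearson r undefined")
        r = None
    else:
        r = float(np.corrcoef(predicted, observed)[0, 1])
    return {"pearson_r": r, "rmse": rmse}
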