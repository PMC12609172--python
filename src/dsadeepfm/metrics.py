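"""The eight evaluation metrics for imbalanced binary classification.

Implemented directly (rank-statistic AUC-ROC, average-precision AUC-PR,
confusion-matrix metrics, Cohen's kappa, balanced accuracy) so they can be
cross-checked against scikit-learn as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricReport", "auc_roc", "auc_pr", "confusion_metrics", "evaluate_predictions"]


@dataclass
class MetricReport:
    auc_roc: float
    auc_pr: float
    acc: float
    precision: float
    recall: float
    f1: float
    kappa: float
    bacc: float
    threshold: float = 0.5
    auc_defined: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def _rankdata_average(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i: j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def auc_roc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC-ROC via the Mann-Whitney rank statistic (tie-corrected)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC-ROC undefined: only one class present")
    ranks = _rankdata_average(s)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_pr(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Average precision: sum over recall steps of (R_i - R_{i-1}) * P_i."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUC-PR undefined: no positive examples")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate only at distinct-threshold boundaries
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def confusion_metrics(y_true, y_pred) -> dict:
    y = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    bacc = 0.5 * (recall + tnr)
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1.0 else 0.0
    return {
        "acc": acc, "precision": precision, "recall": recall,
        "f1": f1, "kappa": kappa, "bacc": bacc,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricReport:
    """All eight metrics from synergy probabilities and binary labels.

    If only one class is present, the two AUCs are reported as NaN with
    `auc_defined=False`; the confusion-matrix metrics are still computed.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    one_class = len(np.unique(y)) < 2
    cm = confusion_metrics(y, (s >= threshold).astype(int))
    return MetricReport(
        auc_roc=float("nan") if one_class else auc_roc(y, s),
        auc_pr=float("nan") if one_class else auc_pr(y, s),
        acc=cm["acc"], precision=cm["precision"], recall=cm["recall"],
        f1=cm["f1"], kappa=cm["kappa"], bacc=cm["bacc"],
        threshold=threshold, auc_defined=not one_class,
    )
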