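"""Evaluation metrics for the three task types (computed on decrypted outputs).

Classification uses one-vs-rest precision/recall/F1 plus the confusion
matrix; regression reports the mean absolute percentage error (MAPE) and the
Pearson correlation per output; binary problems additionally get an ROC curve
from a threshold sweep with trapezoidal area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "evaluate", "mape", "pearson", "roc_curve_points"]


@dataclass
class MetricsReport:
    task: str
    accuracy: float | None = None
    precision: np.ndarray | None = None
    recall: np.ndarray | None = None
    f1: np.ndarray | None = None
    confusion: np.ndarray | None = None
    mape: np.ndarray | None = None
    mape_excluded: int = 0
    pearson: np.ndarray | None = None
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    roc_auc: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"task": self.task}
        for k in ("accuracy", "roc_auc", "mape_excluded"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        for k in ("precision", "recall", "f1", "confusion", "mape", "pearson",
                  "roc_fpr", "roc_tpr"):
            v = getattr(self, k)
            if v is not None:
                out[k] = np.asarray(v).tolist()
        out.update(self.extras)
        return out


def mape(y_true: np.ndarray, y_pred: np.ndarray, zero_tol: float = 1e-12):
    """mean(|y - yhat| / |y|) * 100 per output column.

    Samples with |y| < zero_tol are excluded; the exclusion count is returned
    alongside so silent omissions are visible.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float).T).T
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float).T).T
    ok = np.abs(y_true) >= zero_tol
    excluded = int(np.size(ok) - np.count_nonzero(ok))
    vals = np.full(y_true.shape[1], np.nan)
    for j in range(y_true.shape[1]):
        m = ok[:, j]
        if m.any():
            vals[j] = np.mean(np.abs(y_true[m, j] - y_pred[m, j]) / np.abs(y_true[m, j])) * 100.0
    return vals, excluded


def pearson(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Pearson correlation coefficient per output column."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float).T).T
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float).T).T
    out = np.empty(y_true.shape[1])
    for j in range(y_true.shape[1]):
        a = y_true[:, j] - y_true[:, j].mean()
        b = y_pred[:, j] - y_pred[:, j].mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        out[j] = (a * b).sum() / denom if denom > 0 else np.nan
    return out


def roc_curve_points(y_true: np.ndarray, scores: np.ndarray):
    """ROC by sweeping the decision threshold over the predicted scores."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    P = y.sum()
    N = len(y) - P
    tps = np.cumsum(y)
    fps = np.cumsum(1.0 - y)
    # one point per distinct threshold plus the (0, 0) origin
    s = scores[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / P] if P else np.zeros(len(distinct) + 1)
    fpr = np.r_[0.0, fps[distinct] / N] if N else np.zeros(len(distinct) + 1)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def _one_vs_rest(conf: np.ndarray):
    k = conf.shape[0]
    prec = np.zeros(k)
    rec = np.zeros(k)
    f1 = np.zeros(k)
    for c in range(k):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        prec[c] = tp / (tp + fp) if tp + fp else 0.0
        rec[c] = tp / (tp + fn) if tp + fn else 0.0
        f1[c] = 2 * prec[c] * rec[c] / (prec[c] + rec[c]) if prec[c] + rec[c] else 0.0
    return prec, rec, f1


def evaluate(predictions: np.ndarray, targets: np.ndarray, task: str) -> MetricsReport:
    """Score decrypted predictions against plaintext targets.

    multiclass: predictions are class-probability rows, targets one-hot or
    label vectors.  binary: predictions are positive-class probabilities,
    targets 0/1.  regression: real-valued outputs.
    """
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if task == "multiclass":
        k = predictions.shape[1]
        pred_labels = predictions.argmax(axis=1)
        true_labels = targets.argmax(axis=1) if targets.ndim == 2 else targets.astype(int)
        conf = np.zeros((k, k))
        for t, p in zip(true_labels, pred_labels):
            conf[int(t), int(p)] += 1
        prec, rec, f1 = _one_vs_rest(conf)
        return MetricsReport(
            task=task,
            accuracy=float((pred_labels == true_labels).mean()),
            precision=prec, recall=rec, f1=f1, confusion=conf,
        )
    if task == "binary":
        scores = predictions.ravel()
        true = targets.ravel()
        pred_labels = (scores >= 0.5).astype(int)
        conf = np.zeros((2, 2))
        for t, p in zip(true, pred_labels):
            conf[int(t), int(p)] += 1
        prec, rec, f1 = _one_vs_rest(conf)
        fpr, tpr, auc = roc_curve_points(true, scores)
        return MetricsReport(
            task=task,
            accuracy=float((pred_labels == true).mean()),
            precision=prec, recall=rec, f1=f1, confusion=conf,
            roc_fpr=fpr, roc_tpr=tpr, roc_auc=auc,
        )
    if task == "regression":
        m, excluded = mape(targets, predictions)
        r = pearson(targets, predictions)
        return MetricsReport(task=task, mape=m, mape_excluded=excluded, pearson=r)
    raise ValueError(f"unknown task {task!r}")
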