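"""Confusion-table construction, accuracy and macro-averaged metrics.

Accuracy is trace/total.  Macro precision and recall are unweighted
class means of P_i = TP_i/(TP_i+FP_i) and R_i = TP_i/(TP_i+FN_i); the
default macro-F1 is the harmonic mean of macro-P and macro-R
(2*P*R/(P+R)), which differs from the mean-of-per-class-F1 convention —
both are computed and reported.  A class with a zero denominator scores
0 (conservative and deterministic; micro-averaging equals accuracy and
is not separately exposed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionTable:
    """n x n count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()


def confusion_table(y_true, y_pred, n_classes: int) -> ConfusionTable:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= n_classes
                        or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionTable(counts)


def accuracy(table: ConfusionTable) -> float:
    """Fraction of correctly predicted samples: trace / total."""
    if table.total == 0:
        raise ValueError("accuracy undefined for an empty table")
    return float(table.tp().sum() / table.total)


def _safe_divide(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros(len(num))
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    if not np.all(nz):
        warnings.warn(f"class(es) {np.flatnonzero(~nz).tolist()} have zero "
                      f"denominator for {what}; scoring them 0", stacklevel=3)
    return out


def per_class_metrics(table: ConfusionTable) -> dict[str, np.ndarray]:
    tp, fp, fn = table.tp(), table.fp(), table.fn()
    p = _safe_divide(tp.astype(float), (tp + fp).astype(float), "precision")
    r = _safe_divide(tp.astype(float), (tp + fn).astype(float), "recall")
    f1 = np.zeros(len(p))
    nz = (p + r) > 0
    f1[nz] = 2 * p[nz] * r[nz] / (p[nz] + r[nz])
    return {"precision": p, "recall": r, "f1": f1}


def macro_metrics(table: ConfusionTable) -> tuple[float, float, float]:
    """(macro-P, macro-R, macro-F1) with macro-F1 = 2PR/(P+R)."""
    if table.total == 0:
        raise ValueError("macro metrics undefined for an empty table")
    pc = per_class_metrics(table)
    macro_p = float(pc["precision"].mean())
    macro_r = float(pc["recall"].mean())
    macro_f1 = 0.0
    if macro_p + macro_r > 0:
        macro_f1 = 2 * macro_p * macro_r / (macro_p + macro_r)
    return macro_p, macro_r, macro_f1


def macro_f1_mean_of_class(table: ConfusionTable) -> float:
    """Alternative convention: unweighted mean of per-class F1 scores."""
    return float(per_class_metrics(table)["f1"].mean())


def metrics_report(table: ConfusionTable) -> dict:
    """JSON-ready summary of all classification metrics."""
    macro_p, macro_r, macro_f1 = macro_metrics(table)
    pc = per_class_metrics(table)
    return {
        "accuracy": accuracy(table),
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "macro_f1": macro_f1,
        "macro_f1_mean_of_class": macro_f1_mean_of_class(table),
        "per_class": [
            {"class": i, "precision": float(pc["precision"][i]),
             "recall": float(pc["recall"][i]), "f1": float(pc["f1"][i])}
            for i in range(table.n_classes)
        ],
    }
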