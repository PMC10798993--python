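"""Confusion-matrix scores: per-class F1, macro/micro F1, UA/PA.

Convention: rows of the matrix are the map (predicted) class, columns the
reference (true) class. F1 = 2PR/(P+R); macro averages per-class F1 with
equal class importance, micro pools counts (and equals overall accuracy
for single-label per-pixel data). User's accuracy is the per-class
precision of the map, producer's accuracy its recall. Zero-denominator
cases score 0 and are flagged rather than propagating NaN, so macro
aggregation stays stable when a rare class is absent from a small batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from lufor.scenes import UNLABELED


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) int, rows=predicted, cols=truth

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = c.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int,
    ignore_label: int = UNLABELED,
) -> ConfusionMatrix:
    """Count (predicted, truth) pairs, excluding ignored truth pixels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    valid = truth != ignore_label
    if not valid.any():
        return ConfusionMatrix(np.zeros((n_classes, n_classes), dtype=np.int64))
    # sklearn's convention is rows=true, cols=pred; transpose to rows=pred
    cm = _sk_confusion(truth[valid].ravel(), pred[valid].ravel(),
                       labels=np.arange(n_classes)).T
    return ConfusionMatrix(cm)


def f1_scores(cm: ConfusionMatrix) -> Tuple[np.ndarray, float, float]:
    """(per-class F1, macro F1, micro F1)."""
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c).astype(float)
    mapped = c.sum(axis=1).astype(float)     # row sums: pixels mapped as class
    reference = c.sum(axis=0).astype(float)  # col sums: pixels truly of class
    precision = np.divide(diag, mapped, out=np.zeros_like(diag), where=mapped > 0)
    recall = np.divide(diag, reference, out=np.zeros_like(diag), where=reference > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom,
                   out=np.zeros_like(diag), where=denom > 0)
    macro = float(f1.mean())
    micro = float(diag.sum() / cm.total)  # pooled P == pooled R == accuracy
    return f1, macro, micro


def users_producers(cm: ConfusionMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """(user's accuracy per class, producer's accuracy per class).

    UA_i = c_ii / row_i (precision), PA_j = c_jj / col_j (recall); classes
    never mapped / never present score 0 by convention.
    """
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c).astype(float)
    rows = c.sum(axis=1).astype(float)
    cols = c.sum(axis=0).astype(float)
    ua = np.divide(diag, rows, out=np.zeros_like(diag), where=rows > 0)
    pa = np.divide(diag, cols, out=np.zeros_like(diag), where=cols > 0)
    return ua, pa


def metrics_table(cm: ConfusionMatrix, class_names=None):
    """Tidy per-class table (class, precision, recall, f1, ua, pa) plus a
    summary dict (macro_f1, micro_f1, overall_accuracy)."""
    import pandas as pd

    f1, macro, micro = f1_scores(cm)
    ua, pa = users_producers(cm)
    k = cm.n_classes
    names = class_names if class_names is not None else [str(i) for i in range(k)]
    table = pd.DataFrame({
        "class": names,
        "precision": ua,
        "recall": pa,
        "f1": f1,
        "ua": ua,
        "pa": pa,
    })
    summary = {"macro_f1": macro, "micro_f1": micro, "overall_accuracy": micro}
    return table, summary
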