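"""Confusion matrix, per-class precision/recall/F1 and macro F1.

Macro averaging weighs every class equally, which is the appropriate choice
for heavily imbalanced arrhythmia classes.  Conventions: per-class F1 is 0
when precision + recall is 0; a class absent from both the truth and the
predictions of a fold is excluded from that fold's macro average (it is
neither vacuously perfect nor a failure) and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    confusion: np.ndarray  # (C, C), rows = truth
    precision: np.ndarray  # (C,)
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    fold_id: int = 0


def compute_metrics(
    true_labels, pred_labels, n_classes: int, fold_id: int = 0
) -> MetricsReport:
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {y.shape} vs {p.shape}")
    if y.size and (min(y.min(), p.min()) < 0 or max(y.max(), p.max()) >= n_classes):
        raise ValueError("labels outside 0..C-1")
    C = n_classes
    conf = np.zeros((C, C), dtype=np.int64)
    np.add.at(conf, (y, p), 1)
    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    present = (true_tot > 0) | (pred_tot > 0)
    if not present.all():
        logger.info(
            "classes %s absent from truth and predictions; excluded from macro F1",
            np.flatnonzero(~present).tolist(),
        )
    macro = float(f1[present].mean()) if present.any() else 0.0
    return MetricsReport(conf, precision, recall, f1, macro, fold_id)
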