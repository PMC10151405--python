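"""Classification and prediction metrics.

Accuracy, F1 and AUC are defined directly from the confusion counts / ROC
construction; Pearson correlation is the prediction metric. A Pearson value
for a constant vector is returned as NaN so downstream averaging can skip
and count it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(labels, preds, positive=1) -> ConfusionCounts:
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    if labels.shape != preds.shape:
        raise ValueError("labels and predictions must have the same length")
    pos = labels == positive
    ppos = preds == positive
    return ConfusionCounts(tp=int((pos & ppos).sum()), tn=int((~pos & ~ppos).sum()),
                           fp=int((~pos & ppos).sum()), fn=int((pos & ~ppos).sum()))


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero counts")
    return (c.tp + c.tn) / c.total


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall: TP / (TP + (FP + FN)/2)."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        raise UndefinedMetricError("F1 undefined when TP = FP = FN = 0")
    return c.tp / denom


def auc(scores, labels, positive=1) -> float:
    """Area under the empirical ROC curve via the midrank (Mann-Whitney) form.

    Equals P(score+ > score-) + 0.5 P(tie) over all positive/negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def pearson(a, b) -> float:
    """Product-moment correlation; NaN (logged) if either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.info("constant vector in pearson(); returning NaN")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
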