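"""ROC curves and AUC.

Two independent routes to the AUC are kept deliberately: the trapezoidal
integral of the threshold-swept ROC curve, and the midrank (Mann-Whitney)
statistic ``(sum of positive ranks - n1(n1+1)/2) / (n1 n0)``.  With the
midrank tie convention (a tied positive-negative pair counts 0.5) the two
agree to machine precision, which the tests exploit as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["RocCurve", "roc_curve", "auc_rank"]


@dataclass(frozen=True)
class RocCurve:
    """Ordered (fpr, tpr) points from (0, 0) to (1, 1) with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_tsv(self, path: str | Path) -> None:
        """Write (threshold, fpr, tpr) rows as tab-separated text."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for th, f, t in zip(self.thresholds, self.fpr, self.tpr):
                fh.write(f"{float(th)!r}\t{float(f)!r}\t{float(t)!r}\n")


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to build a ROC curve")
    return scores, labels


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve from per-sample scores and binary labels (positive = 1).

    Points come from sweeping every unique score threshold; the curve is
    anchored at (0, 0) and (1, 1) so trapezoidal integration is well defined
    even for constant scores.
    """
    scores, labels = _validate(scores, labels)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the midrank formula; ties count 0.5 per positive-negative pair."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
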