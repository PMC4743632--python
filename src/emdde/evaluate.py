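"""Scoring method output against simulation ground truth.

Significance calls are strict (``q < threshold``) everywhere, including the
false-positive columns, and the ROC is built over the q-value threshold
sweep from 0 to 1 rather than over raw scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClassLabels

__all__ = ["RocCurve", "confusion_at_q", "roc_auc", "fold_change"]


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion_at_q(q, truth, threshold: float) -> tuple[float, float]:
    """(TPR, FPR) when calling genes with ``q < threshold`` significant."""
    q = np.asarray(q, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if q.shape != truth.shape:
        raise ValueError("q-values and truth flags differ in length")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    n_de = int(truth.sum())
    n_null = truth.size - n_de
    if n_de == 0:
        raise ValueError("TPR undefined: no true DE genes")
    called = q < threshold
    tpr = float((called & truth).sum() / n_de)
    fpr = float((called & ~truth).sum() / n_null) if n_null else 0.0
    return tpr, fpr


def roc_auc(q, truth) -> RocCurve:
    """ROC over the q-threshold sweep, with trapezoid AUC over FPR.

    Thresholds are the sorted unique q-values plus {0, 1}; (0,0) is prepended
    and (1,1) appended so curves from heavily tied q-vectors still span the
    unit square.
    """
    q = np.asarray(q, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("both true-DE and true-null genes are required")
    thresholds = np.unique(np.concatenate([q, [0.0, 1.0]]))
    pts = np.array([confusion_at_q(q, truth, t) for t in thresholds])
    tpr = np.concatenate([[0.0], pts[:, 0], [1.0]])
    fpr = np.concatenate([[0.0], pts[:, 1], [1.0]])
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=np.concatenate([[0.0], thresholds, [np.inf]]),
        auc=auc,
    )


def fold_change(m: pd.DataFrame, labels: ClassLabels, scale: str = "log2") -> pd.Series:
    """Per-gene fold change of class 2 over class 1.

    ``scale='linear'``: ratio of class means (NaN where the class-1 mean is
    0).  ``scale='log2'``: values are already log2, so the ratio is
    ``2**(mean2 - mean1)``.
    """
    mask1, mask2 = labels.masks(m.columns)
    X = m.to_numpy(dtype=float)
    m1 = X[:, mask1].mean(axis=1)
    m2 = X[:, mask2].mean(axis=1)
    if scale == "log2":
        fc = np.exp2(m2 - m1)
    elif scale == "linear":
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(m1 != 0, m2 / m1, np.nan)
    else:
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    return pd.Series(fc, index=m.index, name="fold_change")
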