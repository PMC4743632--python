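"""Permutation null distributions, FDR grids and q-values.

The significance machinery is statistic-agnostic: any object with a
``prepare(X) -> (mask1, mask2) -> scores`` method (see
:class:`emdde.emd.EmdStatistic`) can be plugged in, so the same permutation
q-value procedure serves the EMD score, the Cramér–von Mises statistic and
the SAM-style moderated t.

Null model
----------
Sample labels are permuted as whole columns (class sizes preserved, one
shared permutation across genes per iteration).  The per-gene *median* of the
permuted scores forms the empirical null vector ``M = [m_1..m_N]``.  For a
descending threshold grid ``{T, T-d, ..., d, 0}`` the FDR of gene j at
threshold t_i is::

    FDR_ji = ( sum_k I(m_k > t_i) / sum_k I(score_k > t_i) )   if score_j >= t_i
             1                                                  otherwise

with ratios capped at 1 (and defined as 1 when the denominator is 0), and
``q_j = min_i FDR_ji``.  T defaults to ``round(max score) - 1``, floored at
the grid step so small-score datasets still get a grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import fold_change
from .io import ClassLabels

__all__ = [
    "NullMedians",
    "FdrGrid",
    "permuted_null",
    "fdr_grid",
    "bh_adjust",
    "run_emd",
    "bootstrap_stability",
]


@dataclass(frozen=True)
class NullMedians:
    """Per-gene medians of the permuted statistic.

    When built with ``keep_pooled=True``, ``pooled_sorted`` additionally holds
    the ascending flat vector of *all* permuted scores (n_perm × N values),
    enabling the pooled-null FDR numerator used by the SAM-style pipeline.
    """

    medians: np.ndarray
    n_perm: int
    pooled_sorted: np.ndarray | None = None


@dataclass(frozen=True)
class FdrGrid:
    """Threshold grid with the per-threshold FDR ratio and resulting q-values."""

    thresholds: np.ndarray  # descending, last entry 0
    ratios: np.ndarray  # capped num/den per threshold
    q_values: np.ndarray  # per gene


def _prepare_stat(stat, X: np.ndarray):
    """Accept either a statistic object with .prepare or a pairwise callable."""
    if hasattr(stat, "prepare"):
        return stat.prepare(X)

    def score(mask1, mask2):
        return np.array([stat(row[mask1], row[mask2]) for row in X])

    return score


def permuted_null(
    m: pd.DataFrame,
    labels: ClassLabels,
    stat,
    n_perm: int = 1000,
    seed=None,
    keep_pooled: bool = False,
) -> NullMedians:
    """Median of the statistic over ``n_perm`` random label permutations.

    Each iteration reassigns the class labels over all samples (class sizes
    preserved) and recomputes the statistic for every gene; deterministic for
    a fixed seed.  ``keep_pooled=True`` also retains the sorted pooled
    permutation scores for pooled-null FDR estimation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    mask1, mask2 = labels.masks(m.columns)
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    X = m.to_numpy(dtype=float)
    score = _prepare_stat(stat, X)
    rng = np.random.default_rng(seed)
    n_samples = X.shape[1]
    n1 = int(mask1.sum())
    perm_scores = np.empty((n_perm, X.shape[0]))
    for it in range(n_perm):
        perm = rng.permutation(n_samples)
        p1 = np.zeros(n_samples, dtype=bool)
        p1[perm[:n1]] = True
        perm_scores[it] = score(p1, ~p1)
    pooled = np.sort(perm_scores, axis=None) if keep_pooled else None
    return NullMedians(
        medians=np.median(perm_scores, axis=0), n_perm=n_perm, pooled_sorted=pooled
    )


def fdr_grid(
    obs: np.ndarray,
    null: NullMedians | np.ndarray,
    delta: float = 0.001,
    t_max: float | None = None,
    numerator: str = "median",
) -> FdrGrid:
    """q-values from the descending FDR threshold grid (see module docstring).

    ``numerator='median'`` counts null medians above each threshold (the
    main EMD procedure).  ``numerator='pooled'`` counts all pooled permuted
    scores above the threshold divided by the number of permutations — the
    classic SAM-style expected-false-positive count; it requires a null built
    with ``keep_pooled=True``.
    """
    obs = np.asarray(obs, dtype=float)
    med = null.medians if isinstance(null, NullMedians) else np.asarray(null, float)
    if obs.size == 0:
        raise ValueError("no observed scores")
    if obs.shape != med.shape:
        raise ValueError("observed scores and null medians differ in length")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if numerator not in ("median", "pooled"):
        raise ValueError("numerator must be 'median' or 'pooled'")
    if numerator == "pooled" and (
        not isinstance(null, NullMedians) or null.pooled_sorted is None
    ):
        raise ValueError("pooled numerator needs a null built with keep_pooled=True")
    if t_max is None:
        t_max = max(float(np.round(obs.max())) - 1.0, delta)
    if t_max <= 0:
        t_max = delta
    n_steps = int(np.floor(t_max / delta + 1e-9))
    thresholds = t_max - delta * np.arange(n_steps + 1)
    if thresholds[-1] > 1e-12:
        thresholds = np.append(thresholds, 0.0)
    thresholds[-1] = 0.0

    obs_sorted = np.sort(obs)
    n = obs.size
    if numerator == "median":
        med_sorted = np.sort(med)
        num = n - np.searchsorted(med_sorted, thresholds, side="right")
    else:
        pooled = null.pooled_sorted
        num = (
            pooled.size - np.searchsorted(pooled, thresholds, side="right")
        ) / null.n_perm
    den = n - np.searchsorted(obs_sorted, thresholds, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(den > 0, np.minimum(num / np.maximum(den, 1), 1.0), 1.0)
    # q_j = min over thresholds t_i <= obs_j; thresholds are descending so the
    # applicable set is a suffix -> suffix-minimum of the ratio vector
    suffix_min = np.minimum.accumulate(ratios[::-1])[::-1]
    first_idx = np.searchsorted(-thresholds, -obs, side="left")
    q = np.where(first_idx < thresholds.size, suffix_min[np.minimum(first_idx, thresholds.size - 1)], 1.0)
    return FdrGrid(thresholds=thresholds, ratios=ratios, q_values=q)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, monotone, capped at 1."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _result_table(
    m: pd.DataFrame,
    labels: ClassLabels,
    scores: np.ndarray,
    null_median: np.ndarray,
    q: np.ndarray,
    fc_scale: str,
) -> pd.DataFrame:
    fc = fold_change(m, labels, scale=fc_scale)
    return pd.DataFrame(
        {
            "gene": m.index.to_numpy(),
            "score": scores,
            "null_median": null_median,
            "q_value": q,
            "fold_change": fc.to_numpy(),
        }
    )


def run_emd(
    m: pd.DataFrame,
    labels: ClassLabels,
    bin_width: float = 0.2,
    n_perm: int = 1000,
    seed=None,
    delta: float = 0.001,
    t_max: float | None = None,
    fc_scale: str = "log2",
) -> pd.DataFrame:
    """Full EMD pipeline: observed scores, permutation null, q-values, fold change.

    Returns a table with one row per gene and columns
    ``gene, score, null_median, q_value, fold_change``.
    """
    from .emd import EmdStatistic

    stat = EmdStatistic(bin_width=bin_width)
    mask1, mask2 = labels.masks(m.columns)
    X = m.to_numpy(dtype=float)
    obs = _prepare_stat(stat, X)(mask1, mask2)
    null = permuted_null(m, labels, stat, n_perm=n_perm, seed=seed)
    grid = fdr_grid(obs, null, delta=delta, t_max=t_max)
    return _result_table(m, labels, obs, null.medians, grid.q_values, fc_scale)


def bootstrap_stability(
    m: pd.DataFrame,
    labels: ClassLabels,
    method: str = "emd",
    n_boot: int = 100,
    seed=None,
    alpha: float = 0.05,
    **run_kwargs,
):
    """Within-class bootstrap of the whole pipeline.

    Each iteration resamples samples with replacement within each class
    (class sizes preserved), reruns the method and records the q-values.
    Returns ``(median_q, counts)``: the per-gene median q across iterations
    and the number of genes with ``q < alpha`` in each iteration.
    """
    from . import run  # dispatcher, avoids circular import at module load

    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    mask1, mask2 = labels.masks(m.columns)
    idx1 = np.flatnonzero(mask1)
    idx2 = np.flatnonzero(mask2)
    all_q = np.empty((n_boot, m.shape[0]))
    counts = np.empty(n_boot, dtype=int)
    for it in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx1, size=idx1.size), rng.choice(idx2, size=idx2.size)]
        )
        sub = m.iloc[:, take].copy()
        # resampled columns may repeat; disambiguate the sample ids
        new_ids = [f"{m.columns[t]}__b{k}" for k, t in enumerate(take)]
        sub.columns = new_ids
        sub_labels = ClassLabels(
            mapping={
                s: labels.mapping[m.columns[t]] for s, t in zip(new_ids, take)
            },
            classes=labels.classes,
        )
        res = run(
            sub,
            sub_labels,
            method=method,
            seed=int(rng.integers(2**31 - 1)),
            **run_kwargs,
        )
        all_q[it] = res["q_value"].to_numpy()
        counts[it] = int((all_q[it] < alpha).sum())
    return np.median(all_q, axis=0), counts
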