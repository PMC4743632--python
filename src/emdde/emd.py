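"""Histogram signatures and the Earth mover's distance (1-D Wasserstein-1).

The per-gene test statistic is the EMD between the two classes' expression
histograms.  Two routes compute it:

* :func:`emd_lp` — the transportation linear program, valid for arbitrary
  signatures; this is the slow exact reference.
* :func:`emd_1d` — the closed form ``bin_width * sum |CDF_P - CDF_Q|`` for
  signatures sharing one equally spaced grid; this is what the pipeline uses.

Both signatures are normalized to unit mass, so the EMD denominator
(total flow) is 1 and the score is in the data's expression units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "BinGrid",
    "Signature",
    "TransportPlan",
    "make_common_grid",
    "build_signature",
    "emd_lp",
    "emd_1d",
    "emd_score",
    "BinnedCdfStatistic",
    "EmdStatistic",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class BinGrid:
    """Equally spaced histogram bin centers.

    Bin *i* covers the half-open interval
    ``[centers[i] - width/2, centers[i] + width/2)``; the final bin is closed
    above so every value inside the coverage is assigned exactly once.
    """

    centers: np.ndarray
    width: float

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if self.width <= 0:
            raise ValueError(f"bin width must be positive, got {self.width}")
        if c.ndim != 1 or c.size == 0:
            raise ValueError("grid needs at least one bin center")
        if c.size > 1 and not np.allclose(np.diff(c), self.width, atol=1e-9):
            raise ValueError("bin centers must be equally spaced by the bin width")

    @property
    def n_bins(self) -> int:
        return self.centers.size

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        """Assign values to bins; raises if a value falls outside coverage."""
        v = np.asarray(values, dtype=float)
        idx = np.floor((v - self.centers[0]) / self.width + 0.5).astype(np.int64)
        # final bin closed above; tolerate float round-off at the edges
        edge = 1e-9 * max(1.0, float(np.abs(self.centers).max()))
        low = v < self.centers[0] - self.width / 2 - edge
        high = v > self.centers[-1] + self.width / 2 + edge
        if low.any() or high.any():
            bad = v[low | high][0]
            raise ValueError(f"value {bad} outside grid coverage")
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass(frozen=True)
class Signature:
    """A distribution as weighted bin centers {(p_i, w_i)}, weights summing to 1."""

    centers: np.ndarray
    weights: np.ndarray
    width: float | None = None  # set when built on a BinGrid

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "weights", w)
        if c.shape != w.shape or c.ndim != 1:
            raise ValueError("centers and weights must be 1-D and equally long")
        if (w < -_MASS_TOL).any():
            raise ValueError("signature weights must be nonnegative")
        if abs(w.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"signature weights must sum to 1, got {w.sum()}")


@dataclass(frozen=True)
class TransportPlan:
    """Optimal flow between two signatures with its total cost."""

    flow: np.ndarray  # (m, n) nonnegative
    distances: np.ndarray  # (m, n) ground distances |p_i - q_j|
    cost: float


def make_common_grid(x, y, bin_width: float) -> BinGrid:
    """One grid covering the pooled range of both samples.

    The first center sits at the pooled minimum, so coverage starts at
    ``min - width/2``; centers step by ``bin_width`` until the pooled maximum
    is covered.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled_min = min(x.min(), y.min())
    pooled_max = max(x.max(), y.max())
    span = (pooled_max - pooled_min) / bin_width
    n_bins = int(np.ceil(span - 1e-9)) + 1 if span > 0 else 1
    centers = pooled_min + bin_width * np.arange(n_bins)
    return BinGrid(centers=centers, width=bin_width)


def build_signature(values, grid: BinGrid) -> Signature:
    """Histogram ``values`` on ``grid`` and normalize to unit mass."""
    v = np.asarray(values, dtype=float)
    idx = grid.bin_index(v)
    counts = np.bincount(idx, minlength=grid.n_bins)
    return Signature(
        centers=grid.centers, weights=counts / v.size, width=grid.width
    )


def emd_lp(P: Signature, Q: Signature, return_plan: bool = False):
    """EMD via the transportation linear program (exact reference).

    Minimizes ``sum_ij f_ij |p_i - q_j|`` over nonnegative flows with row sums
    bounded by the source weights, column sums by the sink weights, and total
    flow equal to the smaller total mass; returns cost / total flow.  Accepts
    arbitrary (even unequal-mass) signatures, although the pipeline only ever
    builds unit-mass ones.
    """
    d = np.abs(P.centers[:, None] - Q.centers[None, :])
    m, n = d.shape
    total = min(P.weights.sum(), Q.weights.sum())
    # inequality rows: row sums <= w_p, column sums <= w_q
    rows = np.repeat(np.arange(m), n)
    cols = np.tile(np.arange(n), m)
    a_ub = np.zeros((m + n, m * n))
    a_ub[rows, np.arange(m * n)] = 1.0
    a_ub[m + cols, np.arange(m * n)] = 1.0
    b_ub = np.concatenate([P.weights, Q.weights])
    a_eq = np.ones((1, m * n))
    res = linprog(
        c=d.ravel(),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=[total],
        bounds=(0, None),
        method="highs",
    )
    if not res.success:  # pragma: no cover - infeasibility impossible for valid input
        raise RuntimeError(f"transportation LP failed: {res.message}")
    emd = res.fun / total
    if return_plan:
        return emd, TransportPlan(
            flow=res.x.reshape(m, n), distances=d, cost=float(res.fun)
        )
    return float(emd)


def emd_1d(P: Signature, Q: Signature) -> float:
    """Closed-form EMD for signatures on one shared equally spaced grid.

    ``bin_width * sum_i |cumsum(P)_i - cumsum(Q)_i|`` — the Wasserstein-1
    distance between the two unit-mass histograms.
    """
    if P.centers.shape != Q.centers.shape or not np.allclose(
        P.centers, Q.centers, atol=1e-9
    ):
        raise ValueError("emd_1d requires signatures on the same grid")
    if P.width is None or Q.width is None or not np.isclose(P.width, Q.width):
        raise ValueError("emd_1d requires a shared bin width")
    cdf_diff = np.cumsum(P.weights - Q.weights)
    return float(P.width * np.abs(cdf_diff).sum())


def emd_score(x, y, bin_width: float = 0.2) -> float:
    """Per-gene EMD statistic between two samples of expression values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each class needs at least 2 samples")
    grid = make_common_grid(x, y, bin_width)
    return emd_1d(build_signature(x, grid), build_signature(y, grid))


class BinnedCdfStatistic:
    """Base for vectorized statistics of per-gene binned class CDFs.

    ``prepare(X)`` bins every gene once (each gene gets its own grid, anchored
    at that gene's pooled minimum, shared by both classes and therefore by all
    label permutations) and returns a closure mapping two boolean sample masks
    to the per-gene score vector.  Subclasses reduce the per-bin CDF
    difference to a scalar per gene.
    """

    def __init__(self, bin_width: float = 0.2):
        if bin_width <= 0:
            raise ValueError(f"bin width must be positive, got {bin_width}")
        self.bin_width = bin_width

    def _reduce(self, cdf_diff: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def prepare(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        n_genes = X.shape[0]
        lo = X.min(axis=1, keepdims=True)
        idx = np.floor((X - lo) / self.bin_width + 0.5).astype(np.int64)
        n_bins = int(idx.max()) + 1
        flat = idx + n_bins * np.arange(n_genes, dtype=np.int64)[:, None]
        size = n_genes * n_bins

        def score(mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
            n1 = int(mask1.sum())
            n2 = int(mask2.sum())
            c1 = np.bincount(flat[:, mask1].ravel(), minlength=size)
            c2 = np.bincount(flat[:, mask2].ravel(), minlength=size)
            cdf1 = np.cumsum(c1.reshape(n_genes, n_bins), axis=1) / n1
            cdf2 = np.cumsum(c2.reshape(n_genes, n_bins), axis=1) / n2
            return self._reduce(cdf1 - cdf2)

        return score


class EmdStatistic(BinnedCdfStatistic):
    """Vectorized EMD statistic: ``bin_width * sum_bins |CDF1 - CDF2|``."""

    name = "emd"

    def __call__(self, x, y) -> float:
        return emd_score(x, y, self.bin_width)

    def _reduce(self, cdf_diff: np.ndarray) -> np.ndarray:
        return self.bin_width * np.abs(cdf_diff).sum(axis=1)
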