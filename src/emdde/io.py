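"""Reading, writing and preprocessing of expression matrices and labels.

An expression matrix is a :class:`pandas.DataFrame` with gene identifiers as
the index and sample identifiers as the columns.  Values are either
log-scale intensities / log2 TPM (continuous, possibly negative) or raw
nonnegative normalized read counts, depending on the pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabels",
    "read_expression",
    "read_labels",
    "filter_low_counts",
    "log2_transform",
    "quantile_normalize",
    "write_results",
    "read_results",
    "validate_matrix",
]

RESULT_COLUMNS = ("gene", "score", "null_median", "q_value", "fold_change")


@dataclass(frozen=True)
class ClassLabels:
    """Two-class sample labelling.

    Parameters
    ----------
    mapping
        sample id -> class name, exactly two distinct class names.
    classes
        Ordered pair; ``classes[0]`` is "class 1" (fold-change denominator)
        and ``classes[1]`` is "class 2" (numerator).
    """

    mapping: Mapping[str, str]
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        found = set(self.mapping.values())
        if found != set(self.classes):
            raise ValueError(
                f"labels contain classes {sorted(found)}, expected exactly "
                f"{list(self.classes)}"
            )
        if len(self.classes) != 2 or self.classes[0] == self.classes[1]:
            raise ValueError("exactly two distinct class names are required")
        for c in self.classes:
            if not any(v == c for v in self.mapping.values()):
                raise ValueError(f"class {c!r} has no samples")

    @property
    def class_sizes(self) -> tuple[int, int]:
        vals = list(self.mapping.values())
        return vals.count(self.classes[0]), vals.count(self.classes[1])

    def masks(self, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks over ``sample_ids`` for class 1 and class 2.

        Raises if any sample id has no label.
        """
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValueError(f"samples without a class label: {missing[:5]}")
        lab = np.array([self.mapping[s] for s in sample_ids])
        return lab == self.classes[0], lab == self.classes[1]


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Enforce expression-matrix invariants (unique ids, finite numeric body)."""
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if m.columns.has_duplicates:
        dup = m.columns[m.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    vals = m.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        # locate the first offending cell for the error message
        for j, col in enumerate(m.columns):
            coerced = pd.to_numeric(m[col], errors="coerce")
            bad = coerced.isna() & m[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric value {m.iat[i, j]!r} at gene "
                    f"{m.index[i]!r}, sample {col!r}"
                )
        m = m.astype(float)
        vals = m.to_numpy()
    if not np.isfinite(vals).all():
        i, j = map(int, np.argwhere(~np.isfinite(vals))[0])
        raise ValueError(
            f"missing/non-finite value at gene {m.index[i]!r}, "
            f"sample {m.columns[j]!r}"
        )
    return m.astype(float)


def read_expression(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a genes × samples matrix (first column gene ids, header sample ids)."""
    # detect duplicate sample ids before pandas mangles them to "S1.1"
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split(delimiter)[1:]
                break
        else:
            raise ValueError(f"empty expression file: {path}")
    seen: set[str] = set()
    for s in header:
        if s in seen:
            raise ValueError(f"duplicate sample id: {s!r}")
        seen.add(s)
    m = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return validate_matrix(m)


def read_labels(path, delimiter: str = "\t", classes: tuple[str, str] | None = None) -> ClassLabels:
    """Read a two-column (sample id, class) file into :class:`ClassLabels`.

    With ``classes=None`` the ordered pair is the two class names in order of
    first appearance.
    """
    df = pd.read_csv(path, sep=delimiter, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample id, class")
    # tolerate an optional header line
    sample_col, class_col = df.iloc[:, 0], df.iloc[:, 1]
    mapping = dict(zip(sample_col, class_col))
    if len(mapping) != len(df):
        dup = sample_col[sample_col.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id in labels: {dup!r}")
    distinct = list(dict.fromkeys(class_col))
    if len(distinct) != 2:
        raise ValueError(
            f"exactly two classes required, found {len(distinct)}: {distinct}"
        )
    if classes is None:
        classes = (distinct[0], distinct[1])
    return ClassLabels(mapping=mapping, classes=tuple(classes))


def filter_low_counts(
    m: pd.DataFrame, min_count: float = 20, max_fraction: float = 0.5
) -> pd.DataFrame:
    """Drop genes whose counts fall below ``min_count`` in more than
    ``max_fraction`` of samples.

    Both comparisons are strict: a gene is removed iff
    ``mean(value < min_count) > max_fraction``; the boundary case (exactly
    ``max_fraction``) is retained.  Intended for raw normalized counts,
    before any log transform.
    """
    frac_low = (m.to_numpy() < min_count).mean(axis=1)
    return m.loc[frac_low <= max_fraction]


def log2_transform(m: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Replace every value v by log2(v + pseudocount); rejects negative input."""
    vals = m.to_numpy()
    if (vals < 0).any():
        i, j = map(int, np.argwhere(vals < 0)[0])
        raise ValueError(
            f"negative value {vals[i, j]} at gene {m.index[i]!r}, "
            f"sample {m.columns[j]!r}; log2 transform expects counts >= 0"
        )
    return pd.DataFrame(np.log2(vals + pseudocount), index=m.index, columns=m.columns)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so all samples share one empirical distribution.

    Rank each column, replace rank r by the mean of the r-th order statistics
    across columns.  Ties within a column receive the mean of the normalized
    values over their tied rank span (``method='average'`` ranks).
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.to_numpy(dtype=float)
    order_stats = np.sort(vals, axis=0)
    mean_quantiles = order_stats.mean(axis=1)  # target distribution
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = mean_quantiles
        # tied values share the mean target over their rank span
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def write_results(r: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a result table as TSV with columns gene/score/null_median/q_value/fold_change.

    ``header_lines`` are emitted first, '#'-prefixed, for provenance.
    """
    df = r.copy()
    if "gene" not in df.columns and df.index.name in ("gene", None):
        df = df.reset_index(names="gene")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table is missing columns: {missing}")
    df = df.loc[:, list(RESULT_COLUMNS)]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_results(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
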