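"""emdde: Earth mover's distance differential expression analysis.

Identifies genes whose expression *distributions* differ between two sample
classes, which catches heterogeneity-driven differences (bimodality, subtype
structure) that mean-difference tests miss.  Significance comes from label
permutations: the per-gene median of permuted scores forms an empirical null
from which FDRs and q-values are computed.
"""

from __future__ import annotations

import pandas as pd

from .comparators import run_comparator
from .emd import emd_score
from .io import ClassLabels
from .significance import bootstrap_stability, run_emd

__version__ = "0.1.0"

__all__ = [
    "run",
    "run_emd",
    "run_comparator",
    "bootstrap_stability",
    "emd_score",
    "ClassLabels",
    "__version__",
]


def run(
    m: pd.DataFrame,
    labels: ClassLabels,
    method: str = "emd",
    bin_width: float = 0.2,
    n_perm: int = 1000,
    seed=None,
    delta: float = 0.001,
    t_max: float | None = None,
    fc_scale: str = "log2",
) -> pd.DataFrame:
    """Run a differential-distribution analysis with the chosen statistic.

    ``method`` is one of ``emd`` (the main pipeline), ``cvm``, ``sam``
    (permutation q-values) or ``ks`` (BH-adjusted asymptotic p-values).
    Returns one row per gene: ``gene, score, null_median, q_value,
    fold_change``.
    """
    if method == "emd":
        return run_emd(
            m,
            labels,
            bin_width=bin_width,
            n_perm=n_perm,
            seed=seed,
            delta=delta,
            t_max=t_max,
            fc_scale=fc_scale,
        )
    return run_comparator(
        m,
        labels,
        method=method,
        n_perm=n_perm,
        seed=seed,
        delta=delta,
        t_max=t_max,
        bin_width=bin_width,
        fc_scale=fc_scale,
    )
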