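"""Two-class mixture-of-Gaussians simulation with ground-truth DE flags.

The default study emulates a 16,000-gene, 240-sample two-class experiment
(90 vs 150 samples).  15,000 null genes are i.i.d. N(0,1) in both classes.
The 1,000 differentially expressed genes draw their class-2 values from
N(m, 9) with a per-gene mean m ~ N(0, 0.04), and their class-1 values from
a case-specific Gaussian mixture with component variance 9:

========  ================================================  ==================
case      class-1 mixture                                   heterogeneity
========  ================================================  ==================
1         N(2, 9)                                           none (mean shift)
2         0.5 N(-2, 9) + 0.5 N(2, 9)                        bimodal
3         0.7 N(0, 9) + 0.3 N(4, 9)                         minority subtype
4         0.5 N(-4, 9) + 0.5 N(4, 9)                        wide bimodal
5         1/3 N(-4, 9) + 1/3 N(0, 9) + 1/3 N(4, 9)          trimodal
========  ================================================  ==================

Cases 4 and 5 are mean-matched to class 2, so mean-difference tests see no
signal while the distribution shapes differ strongly.  Cases 2-5 are
representative defaults on a monotone heterogeneity ladder, not transcribed
from any published parameter table.  Component membership is drawn
independently per sample (multinomial), so realized component proportions
fluctuate around the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClassLabels

__all__ = [
    "MixtureComponent",
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_case",
    "builtin_case",
    "sample_size_sweep",
]

#: below this size of the smaller class, histogram-distance calls
#: become unreliable and datasets are flagged
RELIABLE_MIN_CLASS = 30


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError(f"component weight must be in (0, 1], got {self.weight}")
        if self.variance <= 0:
            raise ValueError(f"component variance must be positive, got {self.variance}")


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of one simulated two-class dataset."""

    n_genes: int = 16_000
    n_de: int = 1_000
    n1: int = 90
    n2: int = 150
    null_mean: float = 0.0
    null_var: float = 1.0
    class1_mixture: tuple[MixtureComponent, ...] = (
        MixtureComponent(1.0, 2.0, 9.0),
    )
    class2_var: float = 9.0
    class2_mean_var: float = 0.04  # hyperprior variance of the per-gene mean m
    class_names: tuple[str, str] = ("class1", "class2")

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.n_genes < 1 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("n_genes, n1 and n2 must be positive")
        w = sum(c.weight for c in self.class1_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if self.null_var <= 0 or self.class2_var <= 0 or self.class2_mean_var < 0:
            raise ValueError("variances must be positive")


@dataclass(frozen=True)
class SimulatedDataset:
    matrix: pd.DataFrame
    labels: ClassLabels
    truth: pd.Series  # boolean, True = truly differentially expressed
    metadata: dict = field(default_factory=dict)


def simulate_case(spec: SimulationSpec, seed=None) -> SimulatedDataset:
    """Draw one dataset from ``spec``; bitwise reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    n = spec.n_genes
    n_samples = spec.n1 + spec.n2
    X = rng.normal(
        spec.null_mean, np.sqrt(spec.null_var), size=(n, n_samples)
    )
    de_idx = np.sort(rng.choice(n, size=spec.n_de, replace=False))
    if spec.n_de:
        # class 2: per-gene mean m ~ N(0, class2_mean_var)
        m = rng.normal(0.0, np.sqrt(spec.class2_mean_var), size=spec.n_de)
        X[np.ix_(de_idx, np.arange(spec.n1, n_samples))] = rng.normal(
            m[:, None], np.sqrt(spec.class2_var), size=(spec.n_de, spec.n2)
        )
        # class 1: per-sample component assignment
        weights = np.array([c.weight for c in spec.class1_mixture])
        means = np.array([c.mean for c in spec.class1_mixture])
        sds = np.sqrt([c.variance for c in spec.class1_mixture])
        comp = rng.choice(weights.size, size=(spec.n_de, spec.n1), p=weights)
        X[np.ix_(de_idx, np.arange(spec.n1))] = rng.normal(
            means[comp], sds[comp]
        )
    digits = len(str(n))
    genes = pd.Index([f"g{i:0{digits}d}" for i in range(n)], name="gene")
    samples = [f"s{j:03d}" for j in range(n_samples)]
    matrix = pd.DataFrame(X, index=genes, columns=samples)
    mapping = {
        s: (spec.class_names[0] if j < spec.n1 else spec.class_names[1])
        for j, s in enumerate(samples)
    }
    labels = ClassLabels(mapping=mapping, classes=spec.class_names)
    truth = pd.Series(False, index=genes, name="is_de")
    truth.iloc[de_idx] = True
    meta = {
        "n1": spec.n1,
        "n2": spec.n2,
        "small_group_warning": min(spec.n1, spec.n2) < RELIABLE_MIN_CLASS,
    }
    return SimulatedDataset(matrix=matrix, labels=labels, truth=truth, metadata=meta)


_CASES: dict[int, tuple[MixtureComponent, ...]] = {
    1: (MixtureComponent(1.0, 2.0, 9.0),),
    2: (MixtureComponent(0.5, -2.0, 9.0), MixtureComponent(0.5, 2.0, 9.0)),
    3: (MixtureComponent(0.7, 0.0, 9.0), MixtureComponent(0.3, 4.0, 9.0)),
    4: (MixtureComponent(0.5, -4.0, 9.0), MixtureComponent(0.5, 4.0, 9.0)),
    5: (
        MixtureComponent(1 / 3, -4.0, 9.0),
        MixtureComponent(1 / 3, 0.0, 9.0),
        MixtureComponent(1 / 3, 4.0, 9.0),
    ),
}


def builtin_case(case_id: int, **overrides) -> SimulationSpec:
    """Default spec for heterogeneity case 1..5 (see module docstring)."""
    if case_id not in _CASES:
        raise ValueError(f"unknown case {case_id}; expected 1..5")
    return replace(
        SimulationSpec(class1_mixture=_CASES[case_id]), **overrides
    )


def sample_size_sweep(
    base: SimulationSpec, sizes, seed=None
) -> list[SimulatedDataset]:
    """One dataset per (n1, n2) pair, sharing ``base`` otherwise.

    Datasets whose smaller class is below ``RELIABLE_MIN_CLASS`` carry
    ``metadata['small_group_warning'] = True``.
    """
    for n1, n2 in sizes:
        if n1 < 2 or n2 < 2:
            raise ValueError(f"class sizes must be at least 2, got ({n1}, {n2})")
    seeds = np.random.SeedSequence(seed).spawn(len(sizes))
    return [
        simulate_case(replace(base, n1=n1, n2=n2), seed=s)
        for (n1, n2), s in zip(sizes, seeds)
    ]
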