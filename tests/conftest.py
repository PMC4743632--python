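import numpy as np
import pandas as pd
import pytest

from emdde.io import ClassLabels


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0], [0.5, 1.5, 2.5, 3.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def tiny_labels() -> ClassLabels:
    return ClassLabels(
        mapping={"s1": "A", "s2": "A", "s3": "B", "s4": "B"}, classes=("A", "B")
    )


@pytest.fixture
def small_dataset():
    """40 genes x 24 samples; first 8 genes shifted by +3 in class B."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 24))
    X[:8, 12:] += 3.0
    genes = [f"g{i:02d}" for i in range(40)]
    samples = [f"s{j:02d}" for j in range(24)]
    m = pd.DataFrame(X, index=genes, columns=samples)
    labels = ClassLabels(
        mapping={s: ("A" if j < 12 else "B") for j, s in enumerate(samples)},
        classes=("A", "B"),
    )
    truth = np.array([True] * 8 + [False] * 32)
    return m, labels, truth
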