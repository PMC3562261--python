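import numpy as np
import pytest

from bmsf.datamodel import ExpressionDataset, GeneSubset


@pytest.fixture
def separable_dataset() -> tuple[ExpressionDataset, GeneSubset]:
    """Two well-separated Gaussian classes; first two genes carry the signal."""
    rng = np.random.default_rng(11)
    n_per = 10
    labels = np.repeat([1, -1], n_per)
    signal = np.where(labels[:, None] == 1, 4.0, -4.0) + rng.normal(
        0, 0.5, size=(2 * n_per, 2)
    )
    noise = rng.normal(0, 1, size=(2 * n_per, 6))
    matrix = np.hstack([signal, noise])
    ds = ExpressionDataset(
        matrix=matrix,
        sample_ids=[f"s{i}" for i in range(2 * n_per)],
        gene_ids=[f"g{j}" for j in range(8)],
        labels=labels,
    )
    return ds, GeneSubset([0, 1])


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """12 samples x 5 genes of plain noise, balanced classes."""
    rng = np.random.default_rng(3)
    labels = np.repeat([1, -1], 6)
    return ExpressionDataset(
        matrix=rng.normal(size=(12, 5)),
        sample_ids=[f"s{i}" for i in range(12)],
        gene_ids=[f"g{j}" for j in range(5)],
        labels=labels,
    )
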