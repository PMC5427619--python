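import numpy as np
import pytest

from gsearank import ExpressionDataset


@pytest.fixture
def toy_dataset():
    """One gene, g1=[1,2,3] vs g2=[4,5,6]."""
    return ExpressionDataset(
        np.array([[1.0, 2, 3, 4, 5, 6]]), ["g1"], ["A", "A", "A", "B", "B", "B"]
    )


@pytest.fixture
def random_dataset():
    """Factory for random two-group datasets with distinct values."""

    def make(seed=0, n_genes=15, n1=4, n2=5, loc=8.0, scale=1.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(loc, scale, (n_genes, n1 + n2))
        ids = [f"g{i:03d}" for i in range(n_genes)]
        labels = ["A"] * n1 + ["B"] * n2
        return ExpressionDataset(values, ids, labels)

    return make


def swap_groups(dataset):
    """Same data with the group roles exchanged.

    Group 1 is defined as the first label encountered, so the swap moves the
    former group-2 columns to the front.
    """
    idx = np.r_[
        np.flatnonzero(dataset.group2_mask), np.flatnonzero(dataset.group1_mask)
    ]
    return ExpressionDataset(
        dataset.values[:, idx], dataset.gene_ids, dataset.labels[idx]
    )
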