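import numpy as np
import pandas as pd
import pytest

from diffcoex import ExpressionDataset
from diffcoex.network import CorrelationSet


def make_dataset(
    n_genes=8, samples=(6, 6), seed=0, labels=("c1", "c2")
) -> ExpressionDataset:
    """Unstructured random dataset (exchangeable conditions)."""
    rng = np.random.default_rng(seed)
    cols, cond = [], []
    for lab, m in zip(labels, samples):
        cols += [f"{lab}_s{i}" for i in range(m)]
        cond += [lab] * m
    values = pd.DataFrame(
        rng.standard_normal((n_genes, len(cols))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    return ExpressionDataset(values, pd.Series(cond, index=cols))


def random_correlation_set(p=6, n_conditions=2, seed=0) -> CorrelationSet:
    """Valid random correlation matrices (via sample correlation of data)."""
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i}" for i in range(p)])
    mats = {}
    for k in range(n_conditions):
        x = rng.standard_normal((p, p + 5))
        c = np.corrcoef(x)
        np.fill_diagonal(c, 1.0)
        mats[f"c{k + 1}"] = c
    return CorrelationSet(genes, mats, "pearson")


def pair_correlation_set(c1: float, c2: float) -> CorrelationSet:
    """Two-gene, two-condition correlation set with given off-diagonals."""
    genes = pd.Index(["g0", "g1"])
    return CorrelationSet(
        genes,
        {
            "c1": np.array([[1.0, c1], [c1, 1.0]]),
            "c2": np.array([[1.0, c2], [c2, 1.0]]),
        },
        "pearson",
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
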