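"""Correlation-change networks: per-condition correlations, the
difference-adjacency matrix (standard / strict / multi-condition variants)
and the topological-overlap dissimilarity used for clustering.

The differential coexpression network is built in three steps.  Within each
condition a gene × gene correlation matrix C[k] is computed.  Correlation
change between two conditions is quantified on the signed-r² scale,
s = sign(c)·c², so that changes equal in explained variance get equal
weight, and soft-thresholded with a positive integer exponent β:

    d_ij = ( ½ |s_ij[1] − s_ij[2]| )^β            (standard, 2 conditions)

For n ≥ 2 conditions the change is measured as an RMS deviation from the
consensus signed-r², normalized so that n = 2 reproduces the formula above
exactly.  A stricter variant thresholds the correlations before
differencing.  The resulting adjacency D lives in [0, 1] with zero diagonal
and defines a weighted network of correlation *changes*; the
topological-overlap measure converts it into a dissimilarity in which two
genes are close when their correlation changes involve the same neighbor
genes — the property that lets downstream clustering pick up
module-to-module rewiring, not only within-module decorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import ExpressionDataset

__all__ = [
    "CorrelationSet",
    "DifferenceAdjacency",
    "DissimilarityMatrix",
    "compute_correlations",
    "signed_square",
    "signed_power",
    "difference_adjacency",
    "difference_adjacency_multi",
    "difference_adjacency_strict",
    "tom_dissimilarity",
    "no_tom_dissimilarity",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorrelationSet:
    """One gene × gene correlation matrix per condition."""

    genes: pd.Index
    matrices: dict  # condition label -> (p, p) ndarray
    method: str

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        p = len(self.genes)
        for k, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (p, p):
                raise ValueError(f"condition {k!r}: correlation matrix shape {m.shape}")
            if not np.isfinite(m).all():
                raise ValueError(f"condition {k!r}: non-finite correlations")
            if np.abs(m).max() > 1 + 1e-8:
                raise ValueError(f"condition {k!r}: |correlation| > 1")
            self.matrices[k] = m

    @property
    def conditions(self) -> list:
        return list(self.matrices)

    @property
    def n_conditions(self) -> int:
        return len(self.matrices)

    def matrix(self, condition) -> np.ndarray:
        return self.matrices[condition]

    def subset(self, genes) -> "CorrelationSet":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            bad = pd.Index(genes)[idx < 0].tolist()
            raise KeyError(f"unknown gene ids: {bad[:10]}")
        return CorrelationSet(
            pd.Index(genes),
            {k: m[np.ix_(idx, idx)] for k, m in self.matrices.items()},
            self.method,
        )

    def to_frame(self, condition) -> pd.DataFrame:
        return pd.DataFrame(self.matrices[condition], index=self.genes, columns=self.genes)


def _validate_square(values: np.ndarray, genes: pd.Index, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    p = len(genes)
    if values.shape != (p, p):
        raise ValueError(f"{name}: shape {values.shape} does not match {p} genes")
    if not np.isfinite(values).all():
        raise ValueError(f"{name}: non-finite entries")
    if values.min() < -1e-10 or values.max() > 1 + 1e-10:
        raise ValueError(f"{name}: entries outside [0, 1]")
    return values


@dataclass
class DifferenceAdjacency:
    """Soft-thresholded coexpression-change adjacency D, entries in [0, 1]."""

    genes: pd.Index
    values: np.ndarray
    beta: int
    variant: str = "standard"

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.values = _validate_square(self.values, self.genes, "difference adjacency")
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


@dataclass
class DissimilarityMatrix:
    """Gene × gene dissimilarity T in [0, 1], zero diagonal."""

    genes: pd.Index
    values: np.ndarray
    variant: str = "tom"

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.values = _validate_square(self.values, self.genes, "dissimilarity")
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


# ---------------------------------------------------------------------------
# step 1: per-condition correlation


def _condition_correlation(x: np.ndarray, method: str) -> np.ndarray:
    # x: genes × samples for one condition
    if method == "spearman":
        x = rankdata(x, axis=1)
    c = np.corrcoef(x)
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


def compute_correlations(
    data: ExpressionDataset,
    method: str = "spearman",
    drop_zero_variance: bool = False,
) -> CorrelationSet:
    """Gene–gene correlation matrix within each condition.

    Parameters
    ----------
    data : ExpressionDataset
    method : {"spearman", "pearson"}
        Spearman rank correlation (default) is less sensitive to outliers.
    drop_zero_variance : bool
        A gene with constant expression within any condition has undefined
        correlations.  By default this is a hard error naming the genes;
        with ``drop_zero_variance=True`` such genes are removed with a
        warning instead.

    Returns
    -------
    CorrelationSet
        Symmetric matrices with unit diagonal, one per condition, each
        computed only from that condition's samples.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unsupported correlation method: {method!r}")
    X = data.values.to_numpy(dtype=float)
    genes = data.gene_ids
    cond_cols = {k: data.conditions.to_numpy() == k for k in data.condition_labels}

    bad = np.zeros(len(genes), dtype=bool)
    for k, mask in cond_cols.items():
        bad |= X[:, mask].std(axis=1) == 0.0
    if bad.any():
        offenders = genes[bad].tolist()
        if drop_zero_variance:
            warnings.warn(
                f"dropping {bad.sum()} zero-variance gene(s): {offenders[:10]}",
                UserWarning,
                stacklevel=2,
            )
            X = X[~bad]
            genes = genes[~bad]
            if len(genes) < 2:
                raise ValueError("fewer than 2 genes left after zero-variance filter")
        else:
            raise ValueError(
                "zero within-condition variance (correlation undefined) for "
                f"gene(s): {offenders[:10]}; rerun with drop_zero_variance=True "
                "to remove them"
            )

    matrices = {k: _condition_correlation(X[:, mask], method) for k, mask in cond_cols.items()}
    return CorrelationSet(genes, matrices, method)


# ---------------------------------------------------------------------------
# step 2: difference adjacency


def signed_square(c):
    """Signed squared correlation sign(c)·c² (elementwise)."""
    c = np.asarray(c, dtype=float)
    out = np.sign(c) * c**2
    return out if out.ndim else float(out)


def signed_power(c, beta: int):
    """Sign-preserving soft threshold sign(c)·|c|^β (elementwise)."""
    c = np.asarray(c, dtype=float)
    out = np.sign(c) * np.abs(c) ** beta
    return out if out.ndim else float(out)


def _check_beta(beta: int) -> int:
    if not (isinstance(beta, (int, np.integer)) and beta >= 1):
        raise ValueError(f"beta must be a positive integer, got {beta!r}")
    return int(beta)


def _finalize_adjacency(d: np.ndarray) -> np.ndarray:
    d = np.clip(d, 0.0, 1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def difference_adjacency(cors: CorrelationSet, beta: int = 6) -> DifferenceAdjacency:
    """Two-condition adjacency d = (½|s[1] − s[2]|)^β with s = sign(c)·c²."""
    beta = _check_beta(beta)
    if cors.n_conditions != 2:
        raise ValueError(
            f"difference_adjacency requires exactly 2 conditions, got "
            f"{cors.n_conditions}; use difference_adjacency_multi"
        )
    s1, s2 = (signed_square(cors.matrix(k)) for k in cors.conditions)
    d = (0.5 * np.abs(s1 - s2)) ** beta
    return DifferenceAdjacency(cors.genes, _finalize_adjacency(d), beta, "standard")


def difference_adjacency_multi(cors: CorrelationSet, beta: int = 6) -> DifferenceAdjacency:
    """Multi-condition adjacency: RMS deviation of signed-r² from consensus.

    d = ( sqrt( 1/(2(n−1)) Σ_k (s[k] − c⁰)² ) )^β  with  c⁰ = mean_k s[k].

    For n = 2 this reduces exactly to :func:`difference_adjacency`.
    """
    beta = _check_beta(beta)
    n = cors.n_conditions
    if n < 2:
        raise ValueError("at least 2 conditions required")
    s = np.stack([signed_square(cors.matrix(k)) for k in cors.conditions])
    c0 = s.mean(axis=0)
    d = np.sqrt(((s - c0) ** 2).sum(axis=0) / (2.0 * (n - 1))) ** beta
    return DifferenceAdjacency(cors.genes, _finalize_adjacency(d), beta, "multi")


def difference_adjacency_strict(cors: CorrelationSet, beta: int = 6) -> DifferenceAdjacency:
    """Less sensitive variant d = ½|sign(c[1])|c[1]|^β − sign(c[2])|c[2]|^β|.

    Thresholding before differencing suppresses subtle changes; at β = 2
    it coincides with the standard variant at β = 1.
    """
    beta = _check_beta(beta)
    if cors.n_conditions != 2:
        raise ValueError(
            f"strict variant requires exactly 2 conditions, got {cors.n_conditions}"
        )
    t1, t2 = (signed_power(cors.matrix(k), beta) for k in cors.conditions)
    d = 0.5 * np.abs(t1 - t2)
    return DifferenceAdjacency(cors.genes, _finalize_adjacency(d), beta, "strict")


# ---------------------------------------------------------------------------
# step 3: dissimilarity


def tom_dissimilarity(D: DifferenceAdjacency) -> DissimilarityMatrix:
    """Topological-overlap dissimilarity of the change network.

    t_ij = 1 − (Σ_{k∉{i,j}} d_ik d_kj + d_ij) / (min(k_i, k_j) + 1 − d_ij)

    with connectivity k_i = Σ_{k≠i} d_ik.  Two genes are similar (low t)
    when their correlation changes are shared with the same neighbors, so
    genes rewired towards a common module cluster together even if their
    own pairwise correlation never changes.
    """
    d = D.values
    # diagonal is zero, so the plain matrix product already excludes k = i, j
    numerator = d @ d + d
    k = d.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - d
    t = 1.0 - numerator / denom
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(t, 0.0)
    return DissimilarityMatrix(D.genes, t, "tom")


def no_tom_dissimilarity(D: DifferenceAdjacency) -> DissimilarityMatrix:
    """Simplified dissimilarity T = 1 − D (no topological overlap).

    Cheaper, but sensitive only to direct pairwise correlation change:
    module-to-module rewiring with conserved within-module correlation is
    largely invisible to it.
    """
    t = 1.0 - D.values
    np.fill_diagonal(t, 0.0)
    return DissimilarityMatrix(D.genes, t, "no_tom")
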