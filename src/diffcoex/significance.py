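"""Dispersion statistics and the sample-permutation significance test.

The dispersion of a gene set G summarizes the magnitude of pairwise
correlation change between conditions:

    dispersion(G) = sqrt( (1/|P|) Σ_{(i,j) ∈ P} (c_ij[1] − c_ij[2])² / 2 )

over the unordered distinct pairs P within G (for the module-to-module
version, over the cross pairs A × B).  It is zero exactly when no pairwise
correlation changes, invariant to gene ordering, and bounded by √2 (the
single-pair change from +1 to −1).  With more than two conditions the
squared half-difference generalizes to the mean squared deviation from the
across-condition mean correlation, 1/(n−1) Σ_k (c[k] − c̄)², which reduces
to the two-condition form exactly.

Significance is assessed by permutation: expression is standardized per
gene *within* each condition (so mean/variance differences between
conditions cannot masquerade as correlation change), sample labels are then
reshuffled between conditions preserving group sizes, and the dispersion is
recomputed on each permuted dataset.  The p-value is the fraction of
permutations with dispersion at least as large as observed; zero
exceedances are reported as "< 1/n_perm", never as 0.  Raw per-target
p-values are reported (no multiplicity correction by default, a
Benjamini–Hochberg column is available on request).

Caveat: p-values are calibrated for gene sets fixed *before* looking at
the data.  Modules selected by the clustering on the very same data are,
by construction, the most differentially coexpressed sets in it, so their
permutation p-values are anti-conservative under the null and should be
read as a sanity filter, not as hypothesis tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ModuleAssignment
from .network import CorrelationSet, compute_correlations, _condition_correlation

__all__ = [
    "DispersionResult",
    "dispersion",
    "dispersion_between",
    "permutation_test",
    "results_to_frame",
]


@dataclass
class DispersionResult:
    """Permutation-test outcome for one module or module pair."""

    target: tuple  # (label,) for a module, (labelA, labelB) for a pair
    observed_dispersion: float
    n_perm: int
    n_exceed: int

    def __post_init__(self) -> None:
        self.target = tuple(self.target)
        if not 0 <= self.n_exceed <= self.n_perm:
            raise ValueError("n_exceed must lie in [0, n_perm]")
        if self.observed_dispersion < 0:
            raise ValueError("dispersion must be nonnegative")

    @property
    def target_type(self) -> str:
        return "module" if len(self.target) == 1 else "module_pair"

    @property
    def p_value(self) -> float:
        return self.n_exceed / self.n_perm

    @property
    def p_value_text(self) -> str:
        if self.n_exceed == 0:
            return f"<{1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"


def _pair_dispersion_from_stack(deltas2: np.ndarray) -> float:
    # deltas2: per-pair mean squared deviation values, already on the
    # (c - mean)^2 / (n-1) scale; dispersion is the RMS over pairs
    return float(np.sqrt(deltas2.mean()))


def _squared_change(cors: CorrelationSet) -> np.ndarray:
    """Per-entry mean squared deviation from the across-condition mean.

    Equals (c[1] − c[2])² / 2 for two conditions.
    """
    s = np.stack([cors.matrix(k) for k in cors.conditions])
    n = s.shape[0]
    return ((s - s.mean(axis=0)) ** 2).sum(axis=0) / (n - 1)


def _gene_indices(cors: CorrelationSet, genes) -> np.ndarray:
    idx = cors.genes.get_indexer(pd.Index(genes))
    if (idx < 0).any():
        bad = pd.Index(genes)[idx < 0].tolist()
        raise KeyError(f"unknown gene ids: {bad[:10]}")
    return idx


def dispersion(cors: CorrelationSet, genes) -> float:
    """Within-set dispersion over all unordered distinct pairs in ``genes``."""
    idx = _gene_indices(cors, genes)
    if len(idx) < 2:
        raise ValueError("dispersion needs at least 2 genes")
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate gene ids in the set")
    d2 = _squared_change(cors.subset(pd.Index(genes)))
    iu = np.triu_indices(len(idx), k=1)
    return _pair_dispersion_from_stack(d2[iu])


def dispersion_between(cors: CorrelationSet, genes_a, genes_b) -> float:
    """Module-to-module dispersion over the |A| × |B| cross pairs."""
    a = pd.Index(genes_a)
    b = pd.Index(genes_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both gene sets must be non-empty")
    if len(a.intersection(b)):
        raise ValueError(
            f"gene sets overlap: {a.intersection(b).tolist()[:10]}"
        )
    ia = _gene_indices(cors, a)
    ib = _gene_indices(cors, b)
    d2 = _squared_change(cors)
    return _pair_dispersion_from_stack(d2[np.ix_(ia, ib)].ravel())


# ---------------------------------------------------------------------------
# permutation test


def _standardize_within_condition(data: ExpressionDataset) -> np.ndarray:
    """Per-gene zero-mean unit-variance scaling inside each condition."""
    X = data.values.to_numpy(dtype=float).copy()
    cond = data.conditions.to_numpy()
    for k in data.condition_labels:
        mask = cond == k
        block = X[:, mask]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            genes = data.gene_ids[(sd == 0).ravel()].tolist()
            raise ValueError(
                f"zero within-condition variance in condition {k!r} for "
                f"gene(s): {genes[:10]}"
            )
        X[:, mask] = (block - mu) / sd
    return X


def permutation_test(
    data: ExpressionDataset,
    modules: ModuleAssignment,
    n_perm: int = 1000,
    seed: int = 0,
    include_pairs: bool = True,
    method: str = "spearman",
) -> list[DispersionResult]:
    """Permutation significance of per-module (and module-pair) dispersion.

    Each of ``n_perm`` permutations reassigns the (within-condition
    standardized) samples to conditions uniformly at random, preserving the
    original group sizes, and recomputes every dispersion statistic.
    Reproducible for a fixed ``seed``.

    Returns one :class:`DispersionResult` per non-grey module and, when
    ``include_pairs``, per unordered pair of non-grey modules.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = modules.modules()
    if not labels:
        warnings.warn("no non-grey modules; nothing to test", UserWarning, stacklevel=2)
        return []

    module_genes = {m: modules.genes_in(m) for m in labels}
    used = pd.Index(np.concatenate([g.to_numpy() for g in module_genes.values()]))
    sub = data.subset_genes(used)

    observed_cors = compute_correlations(sub, method=method)
    targets: list[tuple] = [(m,) for m in labels]
    if include_pairs:
        targets += [tuple(p) for p in combinations(labels, 2)]

    def all_dispersions(cors: CorrelationSet) -> np.ndarray:
        vals = []
        for t in targets:
            if len(t) == 1:
                vals.append(dispersion(cors, module_genes[t[0]]))
            else:
                vals.append(
                    dispersion_between(cors, module_genes[t[0]], module_genes[t[1]])
                )
        return np.array(vals)

    observed = all_dispersions(observed_cors)

    X = _standardize_within_condition(sub)
    cond = sub.conditions.to_numpy()
    group_sizes = [int((cond == k).sum()) for k in sub.condition_labels]

    rng = np.random.default_rng(seed)
    n_samples = X.shape[1]
    exceed = np.zeros(len(targets), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        start = 0
        mats = {}
        for k, size in zip(sub.condition_labels, group_sizes):
            cols = perm[start : start + size]
            start += size
            mats[k] = _condition_correlation(X[:, cols], method)
        perm_cors = CorrelationSet(sub.gene_ids, mats, method)
        exceed += all_dispersions(perm_cors) >= observed

    return [
        DispersionResult(t, float(observed[i]), n_perm, int(exceed[i]))
        for i, t in enumerate(targets)
    ]


def results_to_frame(results: list[DispersionResult], bh_column: bool = False) -> pd.DataFrame:
    """Tabulate permutation results (optionally with a BH-adjusted column)."""
    rows = [
        {
            "target_type": r.target_type,
            "labels": "|".join(r.target),
            "observed_dispersion": r.observed_dispersion,
            "n_perm": r.n_perm,
            "n_exceed": r.n_exceed,
            "p_value": r.p_value,
            "p_value_text": r.p_value_text,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if bh_column and len(df):
        p = df["p_value"].to_numpy()
        order = np.argsort(p, kind="stable")
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        df["p_bh"] = adj
    return df
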