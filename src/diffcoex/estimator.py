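"""scikit-learn style estimator wrapping the full differential
coexpression pipeline (correlation → difference adjacency → dissimilarity
→ module detection)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import ExpressionDataset, ModuleAssignment
from .detection import ClusterParams, cluster_modules, module_mean_expression
from .network import (
    compute_correlations,
    difference_adjacency,
    difference_adjacency_multi,
    difference_adjacency_strict,
    no_tom_dissimilarity,
    tom_dissimilarity,
)
from .significance import permutation_test


class DiffCoEx(ClusterMixin, BaseEstimator):
    """Cluster genes by changes in their pairwise coexpression between
    conditions.

    Follows the scikit-learn clusterer protocol, with the twist that the
    objects being clustered are the *features* (genes) of the usual
    ``(n_samples, n_features)`` design matrix, and the per-sample condition
    labels are passed as ``y``.

    Parameters
    ----------
    correlation : {"spearman", "pearson"}, default "spearman"
        Within-condition correlation measure (Spearman reduces sensitivity
        to outliers).
    beta : int, default 6
        Positive integer soft threshold emphasizing large correlation
        changes over small ones; a stringency/tuning parameter — smaller
        values suit larger sample sizes and subtler signals, and module
        significance should always be checked afterwards with
        :meth:`significance`.
    variant : {"standard", "strict", "multi"}, default "standard"
        Difference-adjacency formula.  "standard" and "strict" require
        exactly two conditions; "multi" handles two or more.
    dissimilarity : {"tom", "no_tom"}, default "tom"
        "tom" uses the topological overlap of the change network (sensitive
        to module-to-module rewiring); "no_tom" uses 1 − D directly.
    cut : {"dynamic", "static", "pam"}, default "dynamic"
        Module extraction: adaptive dendrogram decomposition, fixed-height
        cut, or PAM (k-medoids).
    cut_height : float, optional
        Required for ``cut="static"``.
    min_module_size : int, default 20
        Smaller clusters are relabeled ``grey`` (hierarchical cuts only).
    k : int, optional
        Number of clusters, required for ``cut="pam"``.
    min_gap : float, default 0.1
        Branch-separation threshold of the adaptive cut, in robust
        height-range units.
    drop_zero_variance : bool, default False
        Drop genes constant within a condition instead of raising.

    Attributes
    ----------
    labels_ : ndarray of str, shape (n_genes,)
        Module color label per gene (``grey`` = unassigned).
    modules_ : ModuleAssignment
    correlations_ : CorrelationSet
    adjacency_ : DifferenceAdjacency
    dissimilarity_ : DissimilarityMatrix
    gene_ids_ : pandas.Index of the genes actually clustered.

    Examples
    --------
    >>> from diffcoex.simulate import scenario_a, generate
    >>> data, truth = generate(scenario_a(seed=7))
    >>> model = DiffCoEx().fit(data.values.T, data.conditions)
    >>> sorted(set(model.labels_) - {"grey"})   # doctest: +SKIP
    ['turquoise']
    """

    def __init__(
        self,
        correlation: str = "spearman",
        beta: int = 6,
        variant: str = "standard",
        dissimilarity: str = "tom",
        cut: str = "dynamic",
        cut_height: float | None = None,
        min_module_size: int = 20,
        k: int | None = None,
        min_gap: float = 0.1,
        drop_zero_variance: bool = False,
    ):
        self.correlation = correlation
        self.beta = beta
        self.variant = variant
        self.dissimilarity = dissimilarity
        self.cut = cut
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.k = k
        self.min_gap = min_gap
        self.drop_zero_variance = drop_zero_variance

    # -- internals -----------------------------------------------------
    def _as_dataset(self, X, y) -> ExpressionDataset:
        if isinstance(X, ExpressionDataset):
            if y is not None:
                raise ValueError("pass conditions inside the ExpressionDataset OR as y")
            return X
        if y is None:
            raise ValueError("condition labels y are required")
        if isinstance(X, pd.DataFrame):
            values = X.T
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples × genes)")
            values = pd.DataFrame(
                X.T,
                index=pd.Index([f"gene{i + 1}" for i in range(X.shape[1])]),
                columns=pd.Index([f"sample{j + 1}" for j in range(X.shape[0])]),
            )
        conditions = pd.Series(np.asarray(y, dtype=object), index=values.columns)
        return ExpressionDataset(values, conditions)

    def _cluster_params(self) -> ClusterParams:
        method = {
            "dynamic": "hierarchical_dynamic",
            "static": "hierarchical_static",
            "pam": "pam",
        }.get(self.cut)
        if method is None:
            raise ValueError(f"unknown cut method: {self.cut!r}")
        return ClusterParams(
            method=method,
            cut_height=self.cut_height,
            min_module_size=self.min_module_size,
            k=self.k,
            min_gap=self.min_gap,
        )

    # -- API -----------------------------------------------------------
    def fit(self, X, y=None):
        """Run the full pipeline.

        Parameters
        ----------
        X : array-like (n_samples, n_genes), DataFrame (samples × genes)
            or an :class:`ExpressionDataset` (genes × samples).
        y : array-like of condition labels, one per sample (unless ``X``
            is already an :class:`ExpressionDataset`).
        """
        data = self._as_dataset(X, y)
        params = self._cluster_params()  # validate early
        if self.variant in {"standard", "strict"} and len(data.condition_labels) != 2:
            raise ValueError(
                f"variant {self.variant!r} requires exactly 2 conditions; "
                "use variant='multi'"
            )

        cors = compute_correlations(
            data, method=self.correlation, drop_zero_variance=self.drop_zero_variance
        )
        if self.variant == "standard":
            adj = difference_adjacency(cors, self.beta)
        elif self.variant == "strict":
            adj = difference_adjacency_strict(cors, self.beta)
        elif self.variant == "multi":
            adj = difference_adjacency_multi(cors, self.beta)
        else:
            raise ValueError(f"unknown variant: {self.variant!r}")

        if self.dissimilarity == "tom":
            diss = tom_dissimilarity(adj)
        elif self.dissimilarity == "no_tom":
            diss = no_tom_dissimilarity(adj)
        else:
            raise ValueError(f"unknown dissimilarity: {self.dissimilarity!r}")

        modules = cluster_modules(diss, params)

        self.data_ = data
        self.correlations_ = cors
        self.adjacency_ = adj
        self.dissimilarity_ = diss
        self.modules_ = modules
        self.gene_ids_ = modules.gene_ids
        self.labels_ = modules.labels.to_numpy(dtype=object)
        self.n_features_in_ = data.n_genes
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the per-gene module labels."""
        return self.fit(X, y).labels_

    def significance(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        include_pairs: bool = True,
    ):
        """Permutation dispersion test of the fitted modules.

        See :func:`diffcoex.significance.permutation_test`; uses the same
        correlation measure as the fit.
        """
        check_is_fitted(self, "modules_")
        return permutation_test(
            self.data_,
            self.modules_,
            n_perm=n_perm,
            seed=seed,
            include_pairs=include_pairs,
            method=self.correlation,
        )

    def module_means(self) -> pd.DataFrame:
        """Per-module, per-condition mean expression of the fitted modules."""
        check_is_fitted(self, "modules_")
        return module_mean_expression(self.data_, self.modules_)
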