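"""Module detection: hierarchical clustering of the dissimilarity matrix
with adaptive or static tree cutting, or PAM (k-medoids) partitioning.

Hierarchical paths use average linkage on the dissimilarity treated as a
distance.  The adaptive cutter decomposes the dendrogram into branches that
are both large enough (``min_module_size``) and clearly separated from
their surroundings (a merge-height gap criterion on quantile-normalized
heights), which copes with dendrograms whose informative structure occupies
a tiny sliver of the height range — the typical shape of soft-thresholded
difference networks.  Genes in no accepted branch receive the reserved
``grey`` label.  Modules are named by a deterministic color sequence in
order of decreasing size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataset import UNASSIGNED, ExpressionDataset, ModuleAssignment
from .network import DissimilarityMatrix

__all__ = [
    "ClusterParams",
    "cluster_modules",
    "module_mean_expression",
    "MODULE_COLORS",
]

# WGCNA-style color sequence; extended programmatically when exhausted.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]


@dataclass
class ClusterParams:
    """Settings for :func:`cluster_modules`.

    method : {"hierarchical_dynamic", "hierarchical_static", "pam"}
    cut_height : float in (0, 1], required for the static cut.
    min_module_size : smallest accepted module (smaller clusters -> grey).
    k : number of clusters, required for PAM.
    min_gap : adaptive cut only — minimum separation between a branch's top
        internal merge and the height at which it joins the rest of the
        tree, as a fraction of the robust (5th–95th percentile) height range.
    """

    method: str = "hierarchical_dynamic"
    cut_height: Optional[float] = None
    min_module_size: int = 20
    k: Optional[int] = None
    min_gap: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in {"hierarchical_dynamic", "hierarchical_static", "pam"}:
            raise ValueError(f"unknown clustering method: {self.method!r}")
        if self.method == "hierarchical_static":
            if self.cut_height is None or not (0 < self.cut_height <= 1):
                raise ValueError("static cut requires cut_height in (0, 1]")
        if self.method == "pam" and (self.k is None or self.k < 1):
            raise ValueError("pam requires k >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")


def _color_names(n: int) -> list[str]:
    names = [c for c in MODULE_COLORS if c != UNASSIGNED]
    while len(names) < n:
        names.append(f"module{len(names) + 1}")
    return names[:n]


def _name_by_size(raw: np.ndarray, genes: pd.Index) -> ModuleAssignment:
    """Map integer cluster ids (-1 = unassigned) to size-ordered color names."""
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    # descending size, ties by first-appearing (lowest) id for determinism
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    colors = _color_names(len(ids))
    mapping = {ids[i]: colors[rank] for rank, i in enumerate(order)}
    labels = np.array([mapping.get(r, UNASSIGNED) for r in raw], dtype=object)
    return ModuleAssignment(pd.Series(labels, index=genes))


# ---------------------------------------------------------------------------
# adaptive dendrogram decomposition


def _adaptive_cut(Z: np.ndarray, n: int, min_size: int, min_gap: float) -> np.ndarray:
    """Gap-based branch decomposition of an average-linkage dendrogram.

    The tree is walked top-down.  A branch becomes a module when it is
    large enough (>= min_size) and clearly separated from the point where
    it joins the rest of the tree — a merge-height gap of at least
    ``min_gap`` in robust (5th–95th percentile) height-range units —
    *unless* both of its children are themselves well-separated candidate
    modules, in which case the walk recurses to split them.  Genes under
    no accepted branch end up unassigned (-1).
    """
    heights = Z[:, 2]
    q05, q95 = np.quantile(heights, [0.05, 0.95])
    scale = q95 - q05
    if scale <= 0:
        scale = heights.max() - heights.min()
    if scale <= 0:
        scale = 1.0  # degenerate: all merges at one height -> nothing locks

    size = np.ones(2 * n - 1, dtype=np.int64)
    top = np.zeros(2 * n - 1)  # height of a node's own merge (0 for leaves)
    for t in range(n - 1):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        size[n + t] = size[a] + size[b]
        top[n + t] = Z[t, 2]
    children = Z[:, :2].astype(np.int64)

    def separated(node: int, join_height: float) -> bool:
        return size[node] >= min_size and (join_height - top[node]) / scale >= min_gap

    locked: list[int] = []
    root = 2 * n - 2
    # (node, join_height, lockable); the root joins nothing, so it can only
    # be decomposed, never accepted whole
    stack: list[tuple[int, bool]] = [(root, False)]
    while stack:
        node, lockable = stack.pop()
        if node < n:
            continue
        a, b = children[node - n]
        split = separated(a, top[node]) and separated(b, top[node])
        if lockable and not split:
            locked.append(node)
        else:
            stack.append((a, separated(a, top[node])))
            stack.append((b, separated(b, top[node])))

    labels = np.full(n, -1, dtype=np.int64)
    for mod_id, node in enumerate(locked):
        walk = [node]
        while walk:
            x = walk.pop()
            if x < n:
                labels[x] = mod_id
            else:
                walk.extend(children[x - n])
    return labels


# ---------------------------------------------------------------------------
# PAM (k-medoids), deterministic BUILD + SWAP


def _pam(dist: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    n = dist.shape[0]
    if k >= n:
        return np.arange(n, dtype=np.int64)

    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        cand = int(np.argmax(gain))  # np.argmax takes the lowest index on ties
        medoids.append(cand)
        nearest = np.minimum(nearest, dist[cand])

    def cost(meds: list[int]) -> float:
        return float(dist[meds].min(axis=0).sum())

    current = cost(medoids)
    for _ in range(max_iter):
        best_delta, best_swap = -1e-12, None
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = dist[others].min(axis=0) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                delta = current - float(np.minimum(base, dist[h]).sum())
                if delta > best_delta + 1e-15:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        current = cost(medoids)

    medoids = sorted(medoids)
    return np.argmin(dist[medoids], axis=0).astype(np.int64)


# ---------------------------------------------------------------------------
# public API


def cluster_modules(T: DissimilarityMatrix, params: ClusterParams | None = None) -> ModuleAssignment:
    """Cluster the dissimilarity matrix into modules.

    Returns a :class:`ModuleAssignment` in which every cluster smaller than
    ``min_module_size`` is relabeled ``grey`` (hierarchical paths); PAM
    assigns every gene to one of the ``k`` clusters.
    Deterministic for fixed input and parameters.
    """
    params = params or ClusterParams()
    genes = T.genes
    n = len(genes)
    if not np.isfinite(T.values).all():
        raise ValueError("non-finite dissimilarity entries")

    if params.method != "pam" and n < params.min_module_size:
        warnings.warn(
            f"{n} genes < min_module_size={params.min_module_size}; "
            "all genes left unassigned",
            UserWarning,
            stacklevel=2,
        )
        return ModuleAssignment(pd.Series([UNASSIGNED] * n, index=genes, dtype=object))

    if params.method == "pam":
        raw = _pam(T.values, params.k)
        return _name_by_size(raw, genes)

    Z = linkage(squareform(T.values, checks=False), method="average")
    if params.method == "hierarchical_static":
        flat = fcluster(Z, t=params.cut_height, criterion="distance")
        raw = flat.astype(np.int64) - 1
    else:
        raw = _adaptive_cut(Z, n, params.min_module_size, params.min_gap)

    # size filter: clusters below min_module_size become unassigned
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    small = set(ids[counts < params.min_module_size].tolist())
    raw = np.array([-1 if (r in small or r < 0) else r for r in raw], dtype=np.int64)
    return _name_by_size(raw, genes)


def module_mean_expression(
    data: ExpressionDataset, modules: ModuleAssignment
) -> pd.DataFrame:
    """Mean expression per module and condition (``grey`` included).

    Averages over member genes and over the condition's samples; useful to
    verify that differential coexpression is not an artifact of modules
    simply being unexpressed in one condition.
    """
    missing = data.gene_ids.difference(modules.gene_ids)
    if len(missing):
        raise ValueError(f"modules do not cover genes: {missing.tolist()[:10]}")
    labels = modules.labels.loc[data.gene_ids]
    rows = {}
    for mod in modules.modules(include_unassigned=True):
        sub = data.values.loc[labels.index[labels == mod]]
        if sub.empty:
            continue
        rows[mod] = {
            k: float(sub[data.samples_of(k)].to_numpy().mean())
            for k in data.condition_labels
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module_label"
    return out
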