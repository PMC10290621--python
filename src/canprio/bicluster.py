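"""Ward biclustering of z-scored expression with silhouette-selected k.

Rows (genes) are standardized to mean 0 / sample-sd 1, then genes and regions
are each clustered with Ward's minimum-variance linkage on Euclidean
distances (the dissimilarity-squared "ward.D2" convention: two singletons
merge at their Euclidean distance). The number of clusters on each axis is
chosen by maximizing the mean silhouette width of the hierarchical cuts over
a k range, ties going to the smallest k. When region roles are available the
gene clusters are named FF-ANS / FB-ANS according to whether their mean
z-scored expression is higher in feedforward-role or feedback-role regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .errors import ConfigError, ParseError
from .ingest import ExpressionMatrix, RegionSet

__all__ = [
    "ZScoredMatrix",
    "LinkageTree",
    "ClusterAssignment",
    "BiclusterResult",
    "zscore_rows",
    "ward_linkage",
    "cut_tree",
    "silhouette_select_k",
    "bicluster",
    "to_newick",
]


@dataclass
class ZScoredMatrix:
    """Per-row standardized energies; zero-variance genes are set aside."""

    values: pd.DataFrame
    dropped_rows: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class LinkageTree:
    """SciPy linkage matrix plus the leaf identifiers, in row order."""

    linkage: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ConfigError("merge heights are not non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass
class ClusterAssignment:
    axis: str  # "genes" | "regions"
    k: int
    labels: dict[str, int]
    silhouette_by_k: dict[int, float]
    tree: LinkageTree

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.labels), "cluster": list(self.labels.values())}
        )


def zscore_rows(matrix: ExpressionMatrix) -> ZScoredMatrix:
    """Standardize each gene row with the sample (n-1) standard deviation.

    Zero-variance rows cannot be standardized and are moved to
    ``dropped_rows``.
    """
    if matrix.shape[1] < 2:
        raise ConfigError("z-scoring requires at least 2 regions")
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    dropped = list(values.index[sd == 0])
    kept = values.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    if z.empty:
        raise ConfigError("all gene rows have zero variance; nothing to cluster")
    return ZScoredMatrix(values=z, dropped_rows=dropped)


def ward_linkage(values: pd.DataFrame, axis: str = "genes") -> LinkageTree:
    """Ward minimum-variance linkage over rows (genes) or columns (regions).

    Heights follow the ward.D2 convention (classical Ward on the raw
    observations): merging clusters a, b sits at sqrt(2 * ΔSS(a, b)).
    """
    if axis not in ("genes", "regions"):
        raise ConfigError(f"axis must be 'genes' or 'regions', got {axis!r}")
    X = values if axis == "genes" else values.T
    if X.shape[0] < 2:
        raise ConfigError(f"need at least 2 items on axis {axis!r}")
    arr = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParseError("matrix contains NaN/inf; cannot build linkage")
    Z = hierarchy.linkage(arr, method="ward")
    return LinkageTree(linkage=Z, leaf_ids=list(X.index))


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    """Labels for exactly k groups (remove the k-1 highest merges).

    Cluster indices run 1..k in order of first appearance along the tree's
    leaf ordering.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ConfigError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    for leaf in hierarchy.leaves_list(tree.linkage):
        c = int(raw[leaf])
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    return {tree.leaf_ids[i]: relabel[int(raw[i])] for i in range(n)}


def silhouette_select_k(
    values: pd.DataFrame,
    tree: LinkageTree,
    k_min: int = 2,
    k_max: int = 10,
    axis: str = "genes",
) -> ClusterAssignment:
    """Mean-silhouette profile over hierarchical cuts; argmax k (ties -> smallest).

    ``values`` rows must be the items being clustered (pass the transpose for
    regions). Silhouettes use Euclidean distances.
    """
    n = tree.n_leaves
    if n < 3:
        raise ConfigError(f"silhouette selection needs >= 3 items, got {n}")
    if k_min < 2:
        raise ConfigError(f"k_min must be >= 2, got {k_min}")
    k_max = min(k_max, n - 1)
    if k_max < k_min:
        raise ConfigError(f"empty k range [{k_min}, {k_max}]")
    X = values.loc[tree.leaf_ids].to_numpy(dtype=float)
    profile: dict[int, float] = {}
    cuts: dict[int, dict[str, int]] = {}
    for k in range(k_min, k_max + 1):
        labels = cut_tree(tree, k)
        cuts[k] = labels
        arr = np.array([labels[i] for i in tree.leaf_ids])
        profile[k] = float(silhouette_score(X, arr, metric="euclidean"))
    best = min(profile, key=lambda k: (-round(profile[k], 12), k))
    return ClusterAssignment(
        axis=axis, k=best, labels=cuts[best], silhouette_by_k=profile, tree=tree
    )


@dataclass
class BiclusterResult:
    genes: ClusterAssignment
    regions: ClusterAssignment
    z: ZScoredMatrix
    gene_cluster_names: dict[int, str] = field(default_factory=dict)


def _name_gene_clusters(
    z: ZScoredMatrix, genes: ClusterAssignment, regions: RegionSet
) -> dict[int, str]:
    roles = regions.roles()
    ff = [r for r in z.region_ids if roles.get(r) == "feedforward"]
    fb = [r for r in z.region_ids if roles.get(r) == "feedback"]
    names: dict[int, str] = {}
    counts: dict[str, int] = {"FF-ANS": 0, "FB-ANS": 0}
    for c in sorted(set(genes.labels.values())):
        members = genes.members(c)
        block = z.values.loc[members]
        ff_mean = block[ff].to_numpy().mean() if ff else -np.inf
        fb_mean = block[fb].to_numpy().mean() if fb else -np.inf
        base = "FF-ANS" if ff_mean >= fb_mean else "FB-ANS"
        counts[base] += 1
        names[c] = base
    # Disambiguate if several clusters share a name.
    for base in ("FF-ANS", "FB-ANS"):
        if counts[base] > 1:
            i = 0
            for c in sorted(names):
                if names[c] == base:
                    i += 1
                    names[c] = f"{base}-{i}"
    return names


def bicluster(
    matrix: ExpressionMatrix,
    regions: RegionSet | None = None,
    k_min: int = 2,
    k_max: int = 10,
) -> BiclusterResult:
    """Cluster genes (rows) and regions (columns) of the z-scored matrix."""
    z = zscore_rows(matrix)
    gene_tree = ward_linkage(z.values, axis="genes")
    region_tree = ward_linkage(z.values, axis="regions")
    genes = silhouette_select_k(z.values, gene_tree, k_min, k_max, axis="genes")
    region_assign = silhouette_select_k(
        z.values.T, region_tree, k_min, k_max, axis="regions"
    )
    names = _name_gene_clusters(z, genes, regions) if regions is not None else {}
    return BiclusterResult(genes=genes, regions=region_assign, z=z, gene_cluster_names=names)


def to_newick(tree: LinkageTree) -> str:
    """Serialize the linkage tree as Newick with branch lengths from heights."""
    Z = tree.linkage
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return tree.leaf_ids[i].replace(" ", "_")
        a, b, h = int(Z[i - n, 0]), int(Z[i - n, 1]), float(Z[i - n, 2])
        heights[i] = h
        left = f"{node(a)}:{h - heights[a]:.10g}"
        right = f"{node(b)}:{h - heights[b]:.10g}"
        return f"({left},{right})"

    root = n + len(Z) - 1
    return node(root) + ";"
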