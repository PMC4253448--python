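"""Top-variance feature selection, hierarchical clustering, cluster purity.

Complete-linkage agglomeration on Euclidean distances over the 50
highest-variance miRNAs is the unsupervised view of the cohort: sorted
subsets cluster by cell type, and whole blood separates from all of them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import ConfigError, ExpressionMatrix

LINKAGES = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf identities."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: list[str]
    axis: str = "samples"
    method: str = "complete"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        """Cluster label per leaf at the cut yielding ``n_clusters`` clusters."""
        if not 1 <= n_clusters <= len(self.leaf_ids):
            raise ConfigError("n_clusters must be in [1, n_leaves]")
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string of the tree (branch lengths = merge height gaps)."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def top_variance_features(m: ExpressionMatrix, k: int,
                          sample_ids: list[str] | None = None) -> list[str]:
    """The k miRNA ids with the largest sample variance (n-1 denominator)
    across the selected samples; ties break lexicographically by id."""
    if k < 1 or k > m.shape[0]:
        raise ConfigError(f"k must be in [1, {m.shape[0]}]")
    vals = m.values if sample_ids is None else m.values.loc[:, sample_ids]
    var = vals.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda mid: (-var[mid], mid))
    return order[:k]


def hierarchical_cluster(m: ExpressionMatrix, axis: str = "samples",
                         method: str = "complete") -> Dendrogram:
    """Agglomerative clustering on Euclidean distances along one axis."""
    if axis not in ("samples", "mirnas"):
        raise ConfigError("axis must be 'samples' or 'mirnas'")
    if method not in LINKAGES:
        raise ConfigError(f"method must be one of {LINKAGES}")
    data = m.values.to_numpy(dtype=float)
    ids = m.sample_ids if axis == "samples" else m.mirna_ids
    if axis == "samples":
        data = data.T
    if data.shape[0] < 2:
        raise ConfigError(f"need >= 2 items on axis {axis}")
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method=method)
    return Dendrogram(linkage=link, leaf_ids=list(ids), axis=axis, method=method)


def cluster_purity(dend: Dendrogram, labels: dict[str, str], n_clusters: int) -> float:
    """Cut the tree into ``n_clusters`` and score label purity.

    purity = (sum over clusters of the majority-class count) / n_leaves;
    1.0 iff every cluster is single-class.
    """
    unlabeled = [l for l in dend.leaf_ids if l not in labels]
    if unlabeled:
        raise ConfigError(f"unlabeled leaves: {unlabeled[:5]}")
    assignment = dend.cut(n_clusters)
    total = 0
    for _, members in assignment.groupby(assignment):
        counts = pd.Series([labels[s] for s in members.index]).value_counts()
        total += int(counts.iloc[0])
    return total / len(dend.leaf_ids)
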