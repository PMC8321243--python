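"""Unsupervised structure discovery on the effect table.

The cells x conditions amplitude table is standardized per condition
(z-score) and mined three ways: k-means with the cluster count chosen by the
elbow of the within-cluster sum-of-squares curve, Ward hierarchical
clustering of cells or of conditions, and PCA with per-condition percentage
contributions to the leading components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusterResult",
    "Dendrogram",
    "zscore_columns",
    "kmeans_profile",
    "hierarchical_profile",
    "pca_contributions",
]


@dataclass
class ClusterResult:
    assignment: pd.Series  # cell -> cluster id (for the elbow k)
    k: int
    within_ss: pd.Series  # k -> total within-cluster SS
    assignments_by_k: dict[int, np.ndarray]


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix (Ward)
    items: list  # leaf labels in input order
    axis: str  # 'cells' or 'conditions'

    @property
    def leaf_order(self) -> list:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.items)

    def is_clade(self, members: list) -> bool:
        """True if ``members`` form an exact subtree (monophyletic group)."""
        want = {self.items.index(m) for m in members}
        n = len(self.items)
        clusters: list[set[int]] = [{i} for i in range(n)]
        for row in self.linkage:
            merged = clusters[int(row[0])] | clusters[int(row[1])]
            clusters.append(merged)
            if merged == want:
                return True
        return want == set(range(n)) or len(want) == 1

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return str(self.items[node.id])
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def zscore_columns(effects: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Standardize each condition to zero mean, unit SD across cells."""
    sd = effects.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        if not drop_constant:
            raise ValueError(f"zero-variance condition(s): {list(effects.columns[constant])}")
        warnings.warn(
            f"excluding zero-variance condition(s): {list(effects.columns[constant])}",
            stacklevel=2,
        )
        effects = effects.loc[:, ~constant]
        sd = sd[~constant]
    return (effects - effects.mean(axis=0)) / sd


def kmeans_profile(
    effects: pd.DataFrame,
    k_range: range | tuple[int, int] = (1, 10),
    seed: int = 0,
    n_init: int = 25,
) -> ClusterResult:
    """k-means over a range of k; the elbow k maximizes the second
    difference of the within-cluster SS curve (interior k only).

    Columns are z-scored before clustering so every condition weighs
    equally.  Degenerate input (all rows identical) forces k = 1.
    """
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    X = zscore_columns(effects).to_numpy(dtype=float)
    if len(X) < max(k_range):
        raise ValueError(f"need at least {max(k_range)} cells for k up to {max(k_range)}")
    if np.allclose(X, X[0]):
        warnings.warn("all profiles identical; forcing k = 1", stacklevel=2)
        assignment = np.zeros(len(X), dtype=int)
        return ClusterResult(
            assignment=pd.Series(assignment, index=effects.index),
            k=1,
            within_ss=pd.Series({1: 0.0}),
            assignments_by_k={1: assignment},
        )
    within = {}
    labels = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        within[k] = float(km.inertia_)
        labels[k] = km.labels_.copy()
    ks = sorted(within)
    elbow = ks[0]
    if len(ks) >= 3:
        # knee = maximal curvature of the within-SS curve on a log scale:
        # the last k whose drop is large *relative* to the next one; raw
        # second differences peak at k=2 on any steeply decreasing curve
        w = np.log(np.maximum([within[k] for k in ks], 1e-12))
        second_diff = w[:-2] - 2 * w[1:-1] + w[2:]  # at ks[1:-1]
        elbow = ks[1 + int(np.argmax(second_diff))]
    return ClusterResult(
        assignment=pd.Series(labels[elbow], index=effects.index),
        k=elbow,
        within_ss=pd.Series(within),
        assignments_by_k=labels,
    )


def hierarchical_profile(effects: pd.DataFrame, axis: str = "cells") -> Dendrogram:
    """Ward linkage on Euclidean distances of z-scored profiles.

    ``axis='cells'`` clusters rows (cells) on per-condition z-scores;
    ``axis='conditions'`` clusters the condition columns by their z-scored
    response vectors across cells.
    """
    if axis not in ("cells", "conditions"):
        raise ValueError("axis must be 'cells' or 'conditions'")
    Z = zscore_columns(effects)
    if axis == "cells":
        X = Z.to_numpy(dtype=float)
        items = list(effects.index)
    else:
        X = Z.to_numpy(dtype=float).T
        items = list(Z.columns)
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    linkage = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=linkage, items=items, axis=axis)


def pca_contributions(effects: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Percent contribution of each condition to the leading components.

    PCA of the z-scored table; contribution of condition j to component c is
    ``loading(j, c)^2 / sum_j loading(j, c)^2 * 100`` (columns sum to 100).
    Also carries the explained-variance ratio per component.
    """
    Z = zscore_columns(effects)
    if Z.shape[1] < 2 or Z.shape[0] < 3:
        raise ValueError("PCA needs at least 2 conditions and 3 cells")
    n_components = min(n_components, Z.shape[1])
    pca = PCA(n_components=n_components).fit(Z.to_numpy(dtype=float))
    load2 = pca.components_**2  # (components, conditions)
    contrib = 100.0 * load2 / load2.sum(axis=1, keepdims=True)
    out = pd.DataFrame(
        contrib.T,
        index=Z.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out
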