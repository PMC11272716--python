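"""Hierarchical clustering of bioactivity or fingerprint profiles.

Distances between treatment-group (or substance) profiles are clustered
agglomeratively with Ward's criterion in its "ward.D2" convention
(Murtagh & Legendre): squared dissimilarities inside the Lance-Williams
update, square-rooted merge heights.  scipy's ``linkage(..., "ward")`` on a
condensed distance matrix implements exactly this recurrence.

The :class:`Dendrogram` wrapper exposes the merge tree, enumerable cluster
member sets (as integer bitmasks over the leaf order), and annotated Newick
export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = ["Dendrogram", "distance_matrix", "ward_d2_linkage", "enumerate_clusters"]


def distance_matrix(profile, metric: str = "euclidean") -> pd.DataFrame:
    """Pairwise distances between the treatment-group columns of a profile.

    Accepts a :class:`~grouprax.perturbation.TStatProfile` or a plain
    features x objects DataFrame; returns a symmetric zero-diagonal frame
    indexed by the column labels.
    """
    t = profile.t if hasattr(profile, "t") else profile
    X = t.to_numpy(dtype=float).T  # objects x features
    if X.shape[0] < 2:
        raise ValueError("need at least two columns to compute distances")
    if not np.isfinite(X).all():
        raise ValueError("profile contains non-finite values")
    d = squareform(pdist(X, metric=metric))
    return pd.DataFrame(d, index=t.columns, columns=t.columns)


@dataclass
class Dendrogram:
    """Binary merge tree over a fixed, ordered leaf set.

    ``linkage`` is the scipy linkage matrix: row i merges nodes
    ``linkage[i, 0]`` and ``linkage[i, 1]`` (ids < n are leaves, id n+i is
    the cluster formed at row i) at height ``linkage[i, 2]``.
    """

    leaves: list
    linkage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cluster_masks(self) -> list[int]:
        """Member bitmask of each internal node, in merge order (root last)."""
        n = self.n_leaves
        masks = [1 << i for i in range(n)]
        out = []
        for left, right in self.linkage[:, :2].astype(int):
            m = masks[left] | masks[right]
            masks.append(m)
            out.append(m)
        return out

    def members(self, mask: int) -> list:
        """Leaf labels of a cluster bitmask."""
        return [leaf for i, leaf in enumerate(self.leaves) if mask >> i & 1]

    def mask_of(self, members) -> int:
        """Bitmask for a collection of leaf labels."""
        pos = {leaf: i for i, leaf in enumerate(self.leaves)}
        m = 0
        for x in members:
            m |= 1 << pos[x]
        return m

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels from cutting the tree into ``n_clusters``."""
        return hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")

    def to_newick(self, node_labels: dict[int, str] | None = None) -> str:
        """Newick string; optional internal-node labels keyed by cluster mask.

        Supports are conventionally attached as ``AU|BP|SI`` internal node
        labels; branch lengths are derived from merge heights.
        """
        node_labels = node_labels or {}
        tree = hierarchy.to_tree(self.linkage)
        masks = {}

        def mask_of_node(node) -> int:
            if node.id in masks:
                return masks[node.id]
            m = (
                1 << node.id
                if node.is_leaf()
                else mask_of_node(node.left) | mask_of_node(node.right)
            )
            masks[node.id] = m
            return m

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                name = _escape(str(self.leaves[node.id]))
                return f"{name}:{length:g}"
            inner = ",".join([rec(node.left, node.dist), rec(node.right, node.dist)])
            label = _escape(node_labels.get(mask_of_node(node), ""))
            return f"({inner}){label}:{length:g}"

        return rec(tree, tree.dist) + ";"


def _escape(name: str) -> str:
    if any(ch in name for ch in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def ward_d2_linkage(dist: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Agglomerate a distance matrix under Ward's criterion (ward.D2).

    Heights are the square-rooted Ward merge costs, so for singleton merges
    the height equals the input dissimilarity; heights are non-decreasing
    along any root path.
    """
    if isinstance(dist, pd.DataFrame):
        leaves = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        leaves = list(range(d.shape[0]))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix diagonal must be zero")
    Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return Dendrogram(leaves=leaves, linkage=Z)


def enumerate_clusters(dend: Dendrogram, include_root: bool = True) -> list[int]:
    """The n-1 internal-node member bitmasks, in merge order.

    The root (always recovered by any resample) can be excluded from
    support testing with ``include_root=False``.
    """
    masks = dend.cluster_masks()
    return masks if include_root else masks[:-1]
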