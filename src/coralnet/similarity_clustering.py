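"""Habitat similarity trees from community composition.

Habitats are compared by the species-abundance vectors of their rows
(Bray-Curtis on counts by default, Jaccard on presences as an
alternative) and clustered agglomeratively (UPGMA average linkage by
default).  Trees are built for the full community and for the migrant
and resident subsets; habitats that lose all species in a subset are
kept as leaves at the maximal distance 1 so every tree retains the full
habitat set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core_data import CommunityDataset, InteractionMatrix, Residency, subset_by_residency

__all__ = [
    "habitat_distance",
    "build_tree",
    "Dendrogram",
    "similarity_trees",
]

_METRICS = ("bray_curtis", "jaccard")
_LINKAGES = ("average", "complete", "single")


def habitat_distance(
    matrix: InteractionMatrix,
    metric: str = "bray_curtis",
    zero_rows: str = "exclude",
) -> pd.DataFrame:
    """Symmetric habitat x habitat distance matrix.

    ``bray_curtis`` works on counts, ``jaccard`` on presence-absence.
    All-zero rows have no defined composition; with ``zero_rows=
    'exclude'`` they are dropped with a warning, with ``'max'`` they are
    kept at distance 1 from every other habitat (used for residency
    subsets so trees keep all leaves).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if matrix.n_habitats < 2:
        raise ValueError("need at least 2 habitats")
    labels = list(matrix.habitat_labels)
    x = matrix.counts.astype(float)
    empty = x.sum(axis=1) == 0
    if empty.any():
        bad = [lab for lab, e in zip(labels, empty) if e]
        if zero_rows == "exclude":
            warnings.warn(
                f"excluding habitat(s) with no species from distances: {bad}",
                stacklevel=2,
            )
            keep = ~empty
            labels = [lab for lab, e in zip(labels, empty) if not e]
            x = x[keep]
            empty = np.zeros(len(labels), dtype=bool)
        elif zero_rows != "max":
            raise ValueError("zero_rows must be 'exclude' or 'max'")
    if metric == "jaccard":
        x = (x > 0).astype(float)
        d = squareform(pdist(x, metric="jaccard")) if len(labels) > 1 else np.zeros((1, 1))
    else:
        d = squareform(pdist(x, metric="braycurtis"))
    # empty rows (zero_rows='max'): maximal dissimilarity to everything
    if empty.any():
        d[empty, :] = 1.0
        d[:, empty] = 1.0
        np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over habitat leaves.

    ``linkage_matrix`` is the scipy (n-1) x 4 encoding; merge heights are
    cophenetic distances and are non-decreasing from leaves to root for
    average and complete linkage.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray = field(repr=False)
    method: str = "average"
    metric: str = "bray_curtis"

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=list(self.labels), columns=list(self.labels))

    def nearest(self, habitat: str) -> str:
        """Leaf joining ``habitat`` at the smallest cophenetic distance."""
        d = self.cophenetic()[habitat].drop(habitat)
        return str(d.idxmin())

    def furthest(self, habitat: str) -> str:
        d = self.cophenetic()[habitat].drop(habitat)
        return str(d.idxmax())

    def merge_table(self) -> pd.DataFrame:
        z = self.linkage_matrix
        return pd.DataFrame(
            {
                "left": z[:, 0].astype(int),
                "right": z[:, 1].astype(int),
                "height": z[:, 2],
                "size": z[:, 3].astype(int),
            }
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        assert tree is not None
        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"

    def topology(self) -> frozenset[frozenset[str]]:
        """Set of leaf bipartitions (clades), for topology comparison."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        clades = []

        def walk(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset({self.labels[node.id]})
            s = walk(node.left) | walk(node.right)
            clades.append(s)
            return s

        assert tree is not None
        walk(tree)
        return frozenset(clades)


def build_tree(distances: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Cluster a distance matrix into a dendrogram.

    Habitats are processed in sorted label order so the result does not
    depend on input ordering; scipy's agglomerative linkage then breaks
    any remaining ties deterministically.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    d = distances.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    order = sorted(range(len(distances.index)), key=lambda i: str(distances.index[i]))
    labels = tuple(str(distances.index[i]) for i in order)
    d = d[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    return Dendrogram(labels=labels, linkage_matrix=z, method=linkage)


def similarity_trees(
    dataset: CommunityDataset,
    metric: str = "bray_curtis",
    linkage: str = "average",
) -> dict[str, Dendrogram]:
    """Similarity trees for the total, migrant and resident communities."""
    trees = {}
    for name, ds in (
        ("total", dataset),
        ("migrant", subset_by_residency(dataset, Residency.MIGRANT)),
        ("resident", subset_by_residency(dataset, Residency.RESIDENT)),
    ):
        dist = habitat_distance(ds.matrix, metric=metric, zero_rows="max")
        trees[name] = build_tree(dist, linkage=linkage)
    return trees
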