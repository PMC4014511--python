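"""Ward hierarchical clustering of genes on 1 - semantic similarity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .semsim import GeneSimilarityMatrix


def to_distance(sim: GeneSimilarityMatrix | pd.DataFrame) -> pd.DataFrame:
    """d = 1 - similarity, with an exactly zero diagonal."""
    values = sim.values if isinstance(sim, GeneSimilarityMatrix) else sim
    d = 1.0 - values
    np.fill_diagonal(d.values, 0.0)
    return d


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def to_newick(self) -> str:
        """Serialise with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def ward_cluster(d: pd.DataFrame, variant: str = "ward.d2") -> Dendrogram:
    """Agglomerative Ward clustering of a gene x gene distance matrix.

    ``ward.d2`` (default) is Ward's criterion on squared dissimilarities
    (what modern implementations compute); ``ward.d`` applies the
    Lance-Williams Ward update to the dissimilarities as given, matching
    older implementations. Deterministic for a given input order.
    """
    if d.shape[0] < 2:
        raise ValueError("need at least two genes to cluster")
    arr = d.values
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(arr, checks=False)
    if variant == "ward.d2":
        Z = hierarchy.linkage(condensed, method="ward")
    elif variant == "ward.d":
        # ward.D on d == ward.D2 on sqrt(d) with squared merge heights
        Z = hierarchy.linkage(np.sqrt(condensed), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown ward variant {variant!r}")
    return Dendrogram(Z, list(d.index))


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster id (1..k)
    dendrogram: Dendrogram

    @property
    def k(self) -> int:
        return int(self.labels.nunique())


def cut_clusters(dend: Dendrogram, k: int = 5) -> ClusterAssignment:
    """Cut the tree into exactly *k* non-empty clusters.

    Cluster ids are renumbered 1..k in leaf order so runs are comparable.
    """
    n = len(dend.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        # tied merge heights can make maxclust undershoot; fall back to an
        # explicit cut below the (n-k)-th merge height
        heights = dend.linkage[:, 2]
        t = heights[n - k - 1] if k < n else -1.0
        raw = hierarchy.fcluster(dend.linkage, t=t, criterion="distance")
    order = hierarchy.leaves_list(dend.linkage)
    remap: dict[int, int] = {}
    for leaf in order:
        remap.setdefault(int(raw[leaf]), len(remap) + 1)
    labels = pd.Series([remap[int(c)] for c in raw], index=dend.labels, name="cluster")
    return ClusterAssignment(labels, dend)


def summarize_clusters(assign: ClusterAssignment, gene_calls: pd.DataFrame,
                       labels: tuple[str, str] = ("LM", "SM")) -> pd.DataFrame:
    """Per-cluster totals and per-direction gene counts."""
    rows = []
    for cluster, genes in assign.labels.groupby(assign.labels):
        members = genes.index
        dirs = gene_calls.loc[gene_calls.index.intersection(members), "direction"]
        rows.append({
            "cluster": int(cluster),
            "n_genes": len(members),
            f"n_{labels[0]}": int((dirs == labels[0]).sum()),
            f"n_{labels[1]}": int((dirs == labels[1]).sum()),
        })
    return pd.DataFrame(rows).set_index("cluster")
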