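"""Graph clustering, keratinocyte annotation, and sub-state assignment.

Cells are clustered by Leiden community detection (RB-modularity,
resolution 0.5 by default) on a symmetrized k-nearest-neighbour graph in PC
space. The keratinocyte population is the set of clusters in which a strict
majority of cells show up-regulated keratinocyte markers, where
up-regulated means a marker score (mean log-normalized expression of the
marker set) above the cohort-wide median. Keratinocyte cells are then
re-clustered and the resulting sub-states labelled K0, K1, ... in
decreasing size order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np

import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from kerastate.errors import KerastateError

__all__ = [
    "ClusterLabels",
    "AnnotationResult",
    "build_knn_graph",
    "cluster_cells",
    "marker_score",
    "annotate_keratinocytes",
    "assign_substates",
]


@dataclass
class ClusterLabels:
    labels: np.ndarray = field(repr=False)  # contiguous ids from 0
    k_neighbors: int | None = None
    resolution: float = 0.5
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class AnnotationResult:
    cluster_is_keratinocyte: dict[int, bool]
    cell_scores: np.ndarray = field(repr=False)
    keratinocyte_mask: np.ndarray = field(repr=False)  # per cell


def build_knn_graph(coordinates, k: int) -> ig.Graph:
    """Symmetrized kNN graph: edge (i, j) iff either is among the other's
    k nearest Euclidean neighbours. Distance ties break by cell index."""
    coords = np.asarray(coordinates, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise KerastateError(f"build_knn_graph: k={k} must be < n_cells={n}")
    if k < 1:
        raise KerastateError("build_knn_graph: k must be >= 1")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_cells(graph: ig.Graph, resolution: float = 0.5, seed: int = 0) -> ClusterLabels:
    """Leiden community detection maximizing RB-configuration modularity."""
    if graph.vcount() == 0:
        raise KerastateError("cluster_cells: empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    # leidenalg ids are contiguous from 0 already; enforce defensively
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterLabels(labels=labels, resolution=resolution, seed=seed)


def marker_score(normalized, genes, feature_names=None) -> np.ndarray:
    """Mean log-normalized expression of a marker gene set per cell.

    ``genes`` may be integer indices, or gene names resolved against
    ``feature_names``; unknown names raise with the full missing list.
    """
    genes = list(genes)
    if not genes:
        raise KerastateError("marker_score: empty marker set")
    if any(isinstance(g, str) for g in genes):
        if feature_names is None:
            raise KerastateError("marker_score: gene names given but no feature_names")
        lookup = {str(n): i for i, n in enumerate(feature_names)}
        missing = [g for g in genes if str(g) not in lookup]
        if missing:
            raise KerastateError(f"marker_score: unknown genes {missing}")
        genes = [lookup[str(g)] for g in genes]
    idx = np.asarray(genes, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= normalized.shape[1]):
        raise KerastateError("marker_score: gene index out of range")
    sub = normalized[:, idx]
    if sp.issparse(sub):
        return np.asarray(sub.mean(axis=1)).ravel()
    return np.asarray(sub).mean(axis=1)


def annotate_keratinocytes(labels: ClusterLabels, scores) -> AnnotationResult:
    """Flag clusters where a strict majority of cells are up-regulated.

    A cell is up-regulated when its marker score exceeds the cohort-wide
    median; a cluster is keratinocyte when more than half its cells are.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != labels.labels.size:
        raise KerastateError("annotate_keratinocytes: labels and scores length differ")
    up = scores > np.median(scores)
    flags = {}
    for c in range(labels.n_clusters):
        members = labels.labels == c
        flags[c] = bool(up[members].mean() > 0.5)
    mask = np.array([flags[c] for c in labels.labels]) if labels.labels.size else np.zeros(0, bool)
    return AnnotationResult(cluster_is_keratinocyte=flags, cell_scores=scores, keratinocyte_mask=mask)


def assign_substates(
    coordinates, resolution: float = 0.5, seed: int = 0, k: int = 15
) -> np.ndarray:
    """Re-cluster a keratinocyte subset and label sub-states K0, K1, ...

    States are ordered by decreasing cluster size (ties by smaller original
    cluster id), so K0 is always the largest sub-state.
    """
    coords = np.asarray(coordinates, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise KerastateError("assign_substates: need at least 2 cells")
    graph = build_knn_graph(coords, k=min(k, n - 1))
    clusters = cluster_cells(graph, resolution=resolution, seed=seed)
    sizes = np.bincount(clusters.labels, minlength=clusters.n_clusters)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return np.array([f"K{rank[c]}" for c in clusters.labels])
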