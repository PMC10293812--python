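"""Cell clustering: PCA, graph-based community detection, and a
cluster-validity merge.

Leiden community detection on a kNN graph is the field's workhorse, but on
homogeneous data it fragments a single population into several communities.
The clusterer therefore follows Leiden with a merge pass that joins any
pair of clusters lacking distinguishing genes (per-gene rank-sum tests,
BH-adjusted; a pair stays separate only if at least ``merge_min_genes``
genes have q below ``merge_alpha`` and an absolute mean difference above
``merge_min_diff`` on the log-normalized scale). The result is that
planted populations with clear markers stay separate while arbitrary
splits of one population collapse back together. Populations that differ
in fewer than ``merge_min_genes`` genes cannot be kept apart — the cost
of robustness against splits manufactured from grouped outlier cells.
"""

from __future__ import annotations

import logging

import igraph
import leidenalg
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .stats import benjamini_hochberg, rank_sum_vectorized

logger = logging.getLogger(__name__)


class CellClusterer(BaseEstimator, ClusterMixin):
    """Cluster cells from a normalized expression matrix.

    Parameters
    ----------
    n_components
        Number of principal components (must be smaller than the number
    	of cells).
    n_neighbors
        kNN graph degree for Leiden.
    resolution
        Leiden resolution (RBConfiguration partition).
    n_clusters
        If given, KMeans with this many clusters is used instead of
        Leiden (and no merge pass runs).
    merge_indistinct
        Run the cluster-validity merge pass after Leiden.
    random_state
        Seed; results are deterministic for a fixed seed.
    """

    def __init__(
        self,
        n_components: int = 50,
        n_neighbors: int = 15,
        resolution: float = 2.0,
        n_clusters: int | None = None,
        merge_indistinct: bool = True,
        merge_alpha: float = 0.01,
        merge_min_diff: float = 0.5,
        merge_min_genes: int = 5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.n_clusters = n_clusters
        self.merge_indistinct = merge_indistinct
        self.merge_alpha = merge_alpha
        self.merge_min_diff = merge_min_diff
        self.merge_min_genes = merge_min_genes
        self.random_state = random_state

    def fit(self, X, y=None):
        Xd = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)
        n_cells = Xd.shape[0]
        if n_cells < 2:
            raise ValueError("need at least 2 cells")
        n_comp = min(self.n_components, Xd.shape[1])
        if n_cells <= n_comp:
            raise ValueError(
                f"{n_cells} cells is too few for {n_comp} principal components"
            )
        pca = PCA(
            n_components=n_comp, svd_solver="full", random_state=self.random_state
        )
        self.embedding_ = pca.fit_transform(Xd)

        if self.n_clusters is not None:
            if self.n_clusters > n_cells:
                raise ValueError("n_clusters exceeds the number of cells")
            km = KMeans(
                n_clusters=self.n_clusters, n_init=10, random_state=self.random_state
            )
            labels = km.fit_predict(self.embedding_)
        else:
            k = min(self.n_neighbors, n_cells - 1)
            adj = kneighbors_graph(self.embedding_, k, mode="connectivity")
            adj = adj.maximum(adj.T).tocoo()
            edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
            graph = igraph.Graph(n=n_cells, edges=edges)
            part = leidenalg.find_partition(
                graph,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=self.resolution,
                seed=int(self.random_state),
                n_iterations=2,
            )
            labels = np.asarray(part.membership)
            if self.merge_indistinct:
                labels = self._merge(Xd, labels)
            labels = self._refine(labels)

        # relabel by first occurrence for stable, order-independent ids
        order = {}
        out = np.empty(n_cells, dtype=int)
        for i, lab in enumerate(labels):
            if lab not in order:
                order[lab] = len(order)
            out[i] = order[lab]
        self.labels_ = out
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _refine(self, labels, n_iter: int = 3):
        """Nearest-centroid reassignment in PCA space; cleans up single
        boundary cells the graph partition left in the wrong community."""
        labels = labels.copy()
        for _ in range(n_iter):
            ids = np.unique(labels)
            if len(ids) < 2:
                break
            centroids = np.vstack([self.embedding_[labels == c].mean(axis=0) for c in ids])
            d2 = ((self.embedding_[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1)
            new = ids[np.argmin(d2, axis=1)]
            if np.array_equal(new, labels):
                break
            labels = new
        return labels

    # -- merge pass ---------------------------------------------------------
    def _distinct(self, Xd, labels, a, b) -> bool:
        mask = (labels == a) | (labels == b)
        if min((labels == a).sum(), (labels == b).sum()) < 3:
            return False  # too small to defend its separation
        sub = Xd[mask]
        in_a = labels[mask] == a
        _, _, p = rank_sum_vectorized(sub, in_a)
        q = benjamini_hochberg(p)
        diff = np.abs(sub[in_a].mean(axis=0) - sub[~in_a].mean(axis=0))
        # a handful of "significant" genes can be manufactured by grouping
        # outlier cells (selection bias), so separation must be defended by
        # several genes, as real populations are
        n_distinct = int(np.sum((q < self.merge_alpha) & (diff > self.merge_min_diff)))
        return n_distinct >= self.merge_min_genes

    def _merge(self, Xd, labels):
        labels = labels.copy()
        while True:
            ids = np.unique(labels)
            if len(ids) == 1:
                break
            centroids = np.vstack([self.embedding_[labels == i].mean(axis=0) for i in ids])
            d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
            pairs = [(d[i, j], ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
            pairs.sort(key=lambda t: t[0])
            merged = False
            for _, a, b in pairs:
                if not self._distinct(Xd, labels, a, b):
                    labels[labels == b] = a
                    merged = True
                    break
            if not merged:
                break
        return labels


def cluster_cells(X, n_components: int = 50, resolution_or_k=2.0, seed: int = 0) -> np.ndarray:
    """Thin wrapper over :class:`CellClusterer`.

    ``resolution_or_k``: a float is a Leiden resolution, an int a fixed
    KMeans cluster count.
    """
    if isinstance(resolution_or_k, (int, np.integer)) and not isinstance(resolution_or_k, bool):
        est = CellClusterer(
            n_components=n_components, n_clusters=int(resolution_or_k), random_state=seed
        )
    else:
        est = CellClusterer(
            n_components=n_components, resolution=float(resolution_or_k), random_state=seed
        )
    return est.fit_predict(X)
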