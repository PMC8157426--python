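"""Clustering of the learned embedding.

Two default back-ends mirror the two usage scenarios: KMeans when the
expected number of clusters is known, Leiden community detection on a
k-nearest-neighbour graph when it is not.  Five further scikit-learn
clusterers (Birch, Gaussian mixture, MeanShift, spectral, Ward) are exposed
through the same dispatch so any of them can partition the same embedding.
A naive PCA + KMeans baseline on the expression matrix is included for
reference comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import (
    Birch,
    KMeans,
    MeanShift,
    SpectralClustering,
    AgglomerativeClustering,
)
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, Embedding, Partition, ValidationError

_K_REQUIRED = {"kmeans", "birch", "gmm", "spectral", "ward"}
_METHODS = _K_REQUIRED | {"leiden", "meanshift"}


@dataclass
class ClusterParams:
    """Settings for the pluggable clustering step."""

    method: str = "kmeans"
    n_clusters: Optional[int] = None
    max_iter: int = 300
    n_init: int = 10
    n_neighbors: int = 15
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(f"unknown clustering method {self.method!r}")
        if self.method in _K_REQUIRED:
            if self.n_clusters is None:
                raise ValidationError(f"method {self.method!r} requires n_clusters")
            if self.n_clusters < 1:
                raise ValidationError("n_clusters must be >= 1")
        if self.n_neighbors < 2:
            raise ValidationError("n_neighbors must be >= 2")

    def snapshot(self) -> dict:
        return {
            "method": self.method,
            "n_clusters": self.n_clusters,
            "max_iter": self.max_iter,
            "n_init": self.n_init,
            "n_neighbors": self.n_neighbors,
            "resolution": self.resolution,
            "seed": self.seed,
        }


def _as_embedding(emb) -> Embedding:
    if isinstance(emb, Embedding):
        return emb
    z = np.asarray(emb, dtype=float)
    return Embedding(z, np.array([f"cell_{i}" for i in range(z.shape[0])], dtype=object))


def kmeans_cluster(emb, params: ClusterParams) -> Partition:
    """Lloyd's algorithm with k-means++ seeding and ``n_init`` restarts."""
    emb = _as_embedding(emb)
    k = params.n_clusters
    if k is None or k > emb.z.shape[0]:
        raise ValidationError("n_clusters must be set and <= number of cells")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=params.n_init,
        max_iter=params.max_iter,
        random_state=params.seed,
    ).fit(emb.z)
    return Partition(km.labels_, emb.cell_ids, "kmeans", params.snapshot())


def knn_graph(z: np.ndarray, n_neighbors: int):
    """Symmetrised k-nearest-neighbour graph (Euclidean) as an igraph Graph."""
    import igraph as ig

    n = z.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(z)
    _, idx = nn.kneighbors(z)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges))
    return g


def leiden_cluster(emb, params: ClusterParams) -> Partition:
    """Leiden modularity optimisation on the embedding's kNN graph.

    The graph is built on the embedding directly (no PCA step); the number
    of communities is inferred.
    """
    import leidenalg

    emb = _as_embedding(emb)
    n = emb.z.shape[0]
    if n <= params.n_neighbors:
        raise ValidationError("need more cells than n_neighbors")
    g = knn_graph(emb.z, params.n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=params.resolution,
        seed=params.seed,
        n_iterations=2,
    )
    return Partition(
        np.array(part.membership, dtype=int), emb.cell_ids, "leiden", params.snapshot()
    )


def cluster(emb, params: ClusterParams) -> Partition:
    """Dispatch to the named clustering algorithm over the same embedding."""
    emb = _as_embedding(emb)
    method = params.method
    if method == "kmeans":
        return kmeans_cluster(emb, params)
    if method == "leiden":
        return leiden_cluster(emb, params)
    z = emb.z
    k = params.n_clusters
    if method == "birch":
        labels = Birch(n_clusters=k).fit_predict(z)
    elif method == "gmm":
        labels = GaussianMixture(
            n_components=k, max_iter=params.max_iter, random_state=params.seed
        ).fit_predict(z)
    elif method == "meanshift":
        labels = MeanShift().fit_predict(z)
    elif method == "spectral":
        labels = SpectralClustering(
            n_clusters=k,
            random_state=params.seed,
            assign_labels="kmeans",
            n_neighbors=min(params.n_neighbors, z.shape[0] - 1),
        ).fit_predict(z)
    elif method == "ward":
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(z)
    else:  # pragma: no cover - guarded by ClusterParams
        raise ValidationError(f"unknown clustering method {method!r}")
    return Partition(labels, emb.cell_ids, method, params.snapshot())


def naive_baseline(cm: CountMatrix, k: int, seed: int = 0) -> Partition:
    """PCA to 2 components on the preprocessed matrix, then KMeans(k)."""
    from .preprocessing import preprocess

    if k > cm.n_cells:
        raise ValidationError("k must be <= number of cells")
    pm = preprocess(cm)
    comps = PCA(n_components=2, random_state=seed).fit_transform(pm.values)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(comps)
    return Partition(km.labels_, pm.cell_ids, "naive_pca_kmeans", {"k": k, "seed": seed})


class ContrastiveClusterer(ClusterMixin, BaseEstimator):
    """End-to-end estimator: contrastive embedding followed by clustering.

    ``fit(X)`` expects a preprocessed ``(n, d')`` matrix (see
    :class:`~contraclust.preprocessing.CountPreprocessor`); it trains the
    encoder, clusters the embedding and stores ``labels_``, ``embedding_``
    and ``n_clusters_``.
    """

    def __init__(
        self,
        method: str = "kmeans",
        n_clusters: Optional[int] = None,
        n_neighbors: int = 15,
        resolution: float = 1.0,
        layer_sizes=(200, 40, 60),
        epochs: int = 30,
        batch_size: int = 200,
        learning_rate: float = 0.4,
        temperature: float = 0.5,
        mask_ratio: float = 0.9,
        noise_std: float = 0.0,
        random_state: int = 0,
    ):
        self.method = method
        self.n_clusters = n_clusters
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.layer_sizes = layer_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.temperature = temperature
        self.mask_ratio = mask_ratio
        self.noise_std = noise_std
        self.random_state = random_state

    def fit(self, X, y=None):
        from .encoder import ContrastiveEmbedding

        embedder = ContrastiveEmbedding(
            layer_sizes=self.layer_sizes,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            temperature=self.temperature,
            mask_ratio=self.mask_ratio,
            noise_std=self.noise_std,
            random_state=self.random_state,
        )
        z = embedder.fit_transform(X)
        emb = Embedding(z, embedder.cell_ids_)
        params = ClusterParams(
            method=self.method,
            n_clusters=self.n_clusters,
            n_neighbors=self.n_neighbors,
            resolution=self.resolution,
            seed=self.random_state,
        )
        part = cluster(emb, params)
        self.embedder_ = embedder
        self.embedding_ = z
        self.partition_ = part
        self.labels_ = part.labels
        self.n_clusters_ = part.n_clusters
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
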