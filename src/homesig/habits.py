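"""Multivariate habit clustering of daily activity patterns.

Days embedded by a trained autoencoder (see :mod:`homesig.nn`) are
clustered — mean-shift by default, with k-means and spectral options — and
each cluster is summarised by its *prototype*: the mean (or median) of the
member days in the original time x sensor space.  For benchmarking, the
same pipeline can be run on the raw concatenated per-day profiles with the
same Euclidean metric.

The silhouette score is computed in the space each method actually
clusters: the embedding for autoencoder variants, the raw concatenated
space for the baseline — i.e. each method is judged on the geometry it
"sees".  ``coverage_top5`` is the fraction of days falling in the five
largest clusters; a fragmented clustering scores low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import EmbeddingSet

__all__ = ["ClusterResult", "cluster_embeddings", "baseline_raw_clustering"]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-day cluster id
    algorithm: str
    prototypes: dict[int, np.ndarray]  # cluster -> (time, sensors) profile
    silhouette: float
    coverage_top5: float
    n_clusters: int


def _estimate_bandwidth(X: np.ndarray, quantile: float = 0.3) -> float:
    """Nearest-neighbour distance-quantile heuristic for the mean-shift
    bandwidth (scikit-learn's estimator: mean over points of the max
    distance to the nearest ``quantile`` fraction of neighbours)."""
    from sklearn.cluster import estimate_bandwidth

    if X.shape[0] < 2:
        return 0.0
    return float(estimate_bandwidth(X, quantile=quantile))


def _cluster(X: np.ndarray, algorithm: str, params: dict) -> np.ndarray:
    from sklearn.cluster import KMeans, MeanShift, SpectralClustering

    if algorithm == "mean_shift":
        bw = params.get("bandwidth")
        if bw is None:
            bw = _estimate_bandwidth(X, params.get("quantile", 0.3))
        if bw <= 0:
            warnings.warn("zero bandwidth estimate (duplicate points); single cluster")
            return np.zeros(X.shape[0], dtype=int)
        return MeanShift(bandwidth=bw).fit_predict(X)
    if algorithm == "kmeans":
        k = params.get("n_clusters", 5)
        return KMeans(n_clusters=k, random_state=params.get("seed", 0), n_init=10).fit_predict(X)
    if algorithm == "spectral":
        k = params.get("n_clusters", 5)
        return SpectralClustering(
            n_clusters=k, random_state=params.get("seed", 0), assign_labels="discretize"
        ).fit_predict(X)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _result(
    feature_space: np.ndarray,
    days: np.ndarray,
    labels: np.ndarray,
    algorithm: str,
    prototype: str,
) -> ClusterResult:
    from sklearn.metrics import silhouette_score

    uniq, counts = np.unique(labels, return_counts=True)
    protos: dict[int, np.ndarray] = {}
    agg = np.median if prototype == "median" else np.mean
    for c in uniq:
        protos[int(c)] = agg(days[labels == c], axis=0)
    if len(uniq) >= 2:
        sil = float(silhouette_score(feature_space, labels, metric="euclidean"))
    else:
        sil = -1.0  # undefined for a single cluster; worst case by convention
    top5 = float(np.sort(counts)[::-1][:5].sum() / labels.size)
    return ClusterResult(
        labels=labels,
        algorithm=algorithm,
        prototypes=protos,
        silhouette=sil,
        coverage_top5=top5,
        n_clusters=len(uniq),
    )


def cluster_embeddings(
    emb: EmbeddingSet,
    days,
    algorithm: str = "mean_shift",
    prototype: str = "mean",
    **params,
) -> ClusterResult:
    """Cluster autoencoder embeddings; prototypes live in the original space.

    ``days`` are the original (n_days, time, sensors) matrices aligned with
    ``emb.vectors``; silhouette is computed on the embedding.
    """
    X = emb.vectors
    D = np.asarray(days, dtype=float)
    if X.shape[0] != D.shape[0]:
        raise ValueError("embeddings and days must be aligned")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 days to cluster")
    labels = _cluster(X, algorithm, params)
    return _result(X, D, labels, algorithm, prototype)


def baseline_raw_clustering(
    days,
    algorithm: str = "mean_shift",
    prototype: str = "mean",
    **params,
) -> ClusterResult:
    """Identical pipeline on raw concatenated day profiles (no embedding).

    Each day is flattened to one vector (sensors concatenated along time)
    and clustered with the same Euclidean metric; silhouette is computed in
    this raw space.
    """
    D = np.asarray(days, dtype=float)
    if D.ndim != 3 or D.shape[0] < 2:
        raise ValueError("need an (n_days, time, sensors) array with >= 2 days")
    X = D.reshape(D.shape[0], -1)
    labels = _cluster(X, algorithm, params)
    return _result(X, D, labels, algorithm, prototype)
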