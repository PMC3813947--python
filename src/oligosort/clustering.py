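"""k-means partitioning of z-scored spike representations.

Two subalgorithms are provided, named by their distance: ``cityblock``
(L1; cluster centers are per-dimension medians) and ``sqeuclidean``
(squared L2; centers are means).  Lloyd iterations run to a fixed point of
the assignment (or 300 iterations), the best of ``n_restarts`` seeded
restarts by total within-cluster distance wins.  Because the inputs are
z-scored, initial centroids are drawn from N(0,1)^d with a
data-independent RNG; this makes the outcome equivariant under row
permutations.  An empty cluster is reseeded at the currently worst-fit
point.

Cluster separation is summarized by silhouette values
s(i) = (b(i) - a(i)) / max(a(i), b(i)) computed with the clustering metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples

__all__ = ["ClusterModel", "SilhouetteReport", "kmeans", "silhouette"]

_METRICS = {"cityblock", "sqeuclidean"}


@dataclass
class ClusterModel:
    """Result of one k-means run: labels, centroids and bookkeeping."""

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    metric: str
    representation: str
    seed: int
    inertia: float
    n_iter: int = 0

    def cluster_indices(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class SilhouetteReport:
    """Per-spike silhouettes, per-cluster means, and the overall mean."""

    values: np.ndarray
    cluster_means: dict
    overall_mean: float


def _centroid(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cityblock":
        return np.median(points, axis=0)
    return points.mean(axis=0)


def _inertia(dist_to_own: np.ndarray) -> float:
    return float(dist_to_own.sum())


def kmeans(
    z: np.ndarray,
    k: int,
    metric: str = "cityblock",
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    representation: str = "features",
) -> ClusterModel:
    """Lloyd-style k-means under the chosen metric; best of ``n_restarts``."""
    z = np.asarray(z, dtype=float)
    n, d = z.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(max(1, n_restarts)):
        centroids = rng.standard_normal((k, d))
        labels = np.full(n, -1, dtype=int)
        for it in range(1, max_iter + 1):
            dist = cdist(z, centroids, metric=metric)
            new_labels = dist.argmin(axis=1)
            own = dist[np.arange(n), new_labels]
            # reseed empty clusters at the worst-fit point
            for c in range(k):
                if not (new_labels == c).any():
                    far = int(np.argmax(own))
                    centroids[c] = z[far]
                    dist = cdist(z, centroids, metric=metric)
                    new_labels = dist.argmin(axis=1)
                    own = dist[np.arange(n), new_labels]
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                centroids[c] = _centroid(z[labels == c], metric)
        dist = cdist(z, centroids, metric=metric)
        labels = dist.argmin(axis=1)
        inertia = _inertia(dist[np.arange(n), labels])
        if best is None or inertia < best[0]:
            best = (inertia, labels.copy(), centroids.copy(), it)

    inertia, labels, centroids, n_iter = best
    return ClusterModel(
        labels=labels,
        centroids=centroids,
        k=k,
        metric=metric,
        representation=representation,
        seed=seed,
        inertia=inertia,
        n_iter=n_iter,
    )


def silhouette(z: np.ndarray, labels: np.ndarray, metric: str = "cityblock") -> SilhouetteReport:
    """Silhouette values under the clustering metric.

    A single cluster yields all-zero values with a warning; singleton
    clusters score 0 by convention.
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        warnings.warn("silhouette undefined for a single cluster; returning zeros")
        values = np.zeros(len(labels))
    else:
        sk_metric = "manhattan" if metric == "cityblock" else metric
        values = silhouette_samples(z, labels, metric=sk_metric)
    cluster_means = {int(c): float(values[labels == c].mean()) for c in uniq}
    return SilhouetteReport(
        values=values,
        cluster_means=cluster_means,
        overall_mean=float(values.mean()),
    )
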