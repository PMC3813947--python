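"""Per-cluster PCA with Hotelling T² homogeneity selection.

Within one k-means cluster, spikes are assumed to scatter around the
centroid with an approximately multivariate-normal distribution.  T² is the
squared Mahalanobis distance computed in the PCA basis,

    T²(x) = sum_j score_j(x)² / λ_j,

summed over the retained components.  Waveforms whose T² exceeds the
cutoff at the configured coverage scope (default 99.99%) are "T²-unselected"
outliers handed to the subtraction algorithm; the rest are kept as the
homogeneous core of the cluster.  With estimated mean and covariance the
null distribution of T² is p(n-1)/(n-p) F(p, n-p), whose high quantile is
used as the cutoff (χ²_p in the large-n limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

__all__ = ["PCAModel", "pca_fit", "select_by_t2", "t2_cutoff"]

#: relative eigenvalue floor for retaining components
_EIGENVALUE_FLOOR = 1e-10


@dataclass
class PCAModel:
    """Centered PCA of one cluster plus per-spike T² distances."""

    center: np.ndarray
    loadings: np.ndarray  # (n_components, d), orthonormal rows
    eigenvalues: np.ndarray
    n_components: int
    t2: np.ndarray
    t2_cutoff: float
    scope: float
    n_fit: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.center) @ self.loadings.T

    def t2_of(self, x: np.ndarray) -> np.ndarray:
        scores = self.transform(x)
        return (scores**2 / self.eigenvalues).sum(axis=1)


def t2_cutoff(n: int, p: int, scope: float) -> float:
    """T² quantile at coverage ``scope`` for estimated mean/covariance."""
    if n - p <= 0:
        return float(stats.chi2.ppf(scope, p))
    return float(p * (n - 1) / (n - p) * stats.f.ppf(scope, p, n - p))


def pca_fit(cluster_data: np.ndarray, scope: float = 0.9999) -> PCAModel:
    """Fit a centered PCA to one cluster and score every spike's T².

    Requires more spikes than dimensions and non-zero variance.  Components
    with eigenvalues below 1e-10 of the leading one are dropped (with a
    warning when that truncates the basis).
    """
    x = np.asarray(cluster_data, dtype=float)
    n, d = x.shape
    if n <= d:
        raise ValueError(f"cluster size ({n}) must exceed dimension ({d})")
    pca = PCA(n_components=min(n - 1, d), svd_solver="full")
    scores = pca.fit_transform(x)
    lam = pca.explained_variance_
    if lam[0] <= 0:
        raise ValueError("zero-variance cluster: T² undefined")
    keep = lam > _EIGENVALUE_FLOOR * lam[0]
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} near-zero-variance component(s)"
        )
    lam = lam[keep]
    scores = scores[:, keep]
    p = int(lam.size)
    t2 = (scores**2 / lam).sum(axis=1)
    return PCAModel(
        center=pca.mean_,
        loadings=pca.components_[keep],
        eigenvalues=lam,
        n_components=p,
        t2=t2,
        t2_cutoff=t2_cutoff(n, p, scope),
        scope=scope,
        n_fit=n,
    )


def select_by_t2(
    cluster_data: np.ndarray,
    model: PCAModel | None = None,
    scope: float = 0.9999,
    iterate: bool = False,
    max_rounds: int = 20,
) -> tuple[np.ndarray, np.ndarray, PCAModel]:
    """Split a cluster into T²-selected spikes and T²-unselected outliers.

    Returns ``(selected_idx, unselected_idx, model)``.  By default this is a
    single fit-and-flag pass; ``iterate=True`` refits on the selected set
    until the flagged set is stable.
    """
    x = np.asarray(cluster_data, dtype=float)
    if model is None:
        model = pca_fit(x, scope=scope)
    flagged = model.t2 > model.t2_cutoff
    if iterate:
        for _ in range(max_rounds):
            kept = np.flatnonzero(~flagged)
            if kept.size <= x.shape[1]:
                break
            model = pca_fit(x[kept], scope=scope)
            t2_all = model.t2_of(x)
            new_flagged = t2_all > model.t2_cutoff
            if (new_flagged == flagged).all():
                break
            flagged = new_flagged
    return np.flatnonzero(~flagged), np.flatnonzero(flagged), model
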