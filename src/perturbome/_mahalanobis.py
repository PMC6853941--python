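"""PCA-reduced Mahalanobis distances.

Both perturbation strength and interaction significance are measured as a
Mahalanobis distance of an observation from an empirical reference cloud
(DMSO control wells, or the non-interaction point cloud).  To stabilise the
covariance estimate the reference is first projected onto the smallest
number of principal components that collectively explain a target fraction
of its variance; the distance is computed in that reduced space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PCAMahalanobis", "pca_mahalanobis", "pca_basis", "mahalanobis_in_basis"]


@dataclass(frozen=True)
class PCAMahalanobis:
    """A Mahalanobis metric fitted to a reference point cloud.

    Attributes
    ----------
    n_components:
        Number of principal components retained.
    explained_variance:
        Fraction of the reference variance captured by those components.
    """

    mean: np.ndarray
    components: np.ndarray        # (k, d) projection matrix
    precision: np.ndarray         # (k, k) inverse covariance in reduced space
    n_components: int
    explained_variance: float

    def distance(self, x: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of one point (d,) or many points (m, d)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        z = (np.atleast_2d(x) - self.mean) @ self.components.T
        d2 = np.einsum("ij,jk,ik->i", z, self.precision, z)
        d = np.sqrt(np.maximum(d2, 0.0))
        return float(d[0]) if single else d


def pca_mahalanobis(
    reference: np.ndarray,
    variance_target: float = 0.90,
    ridge: float = 1e-8,
) -> PCAMahalanobis:
    """Fit a PCA-reduced Mahalanobis metric to ``reference`` points.

    Parameters
    ----------
    reference:
        (n, d) array of reference observations; ``n`` should exceed the
        number of retained components for the covariance to be meaningful.
    variance_target:
        Smallest cumulative explained-variance fraction at which the
        component count is truncated.
    ridge:
        Diagonal regularisation added to the reduced covariance.  The
        reduced covariance is diagonal (principal axes), so this only
        guards against components with numerically zero variance.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 2 or reference.shape[0] < 2:
        raise ValueError("reference must be a 2-D array with at least 2 rows")
    n, d = reference.shape
    max_k = min(n - 1, d)
    pca = PCA(n_components=max_k, svd_solver="full")
    pca.fit(reference)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target) + 1)
    k = min(k, max_k)
    components = pca.components_[:k]
    projected = (reference - pca.mean_) @ components.T
    cov = np.cov(projected, rowvar=False)
    cov = np.atleast_2d(cov) + ridge * np.eye(k)
    precision = np.linalg.inv(cov)
    return PCAMahalanobis(
        mean=pca.mean_,
        components=components,
        precision=precision,
        n_components=k,
        explained_variance=float(cum[k - 1]),
    )


def pca_basis(points: np.ndarray, variance_target: float = 0.90) -> tuple[np.ndarray, float]:
    """Principal-axis projection matrix explaining ``variance_target`` of
    the variance of ``points``; returns (components (k, d), explained)."""
    points = np.asarray(points, dtype=float)
    max_k = min(points.shape[0] - 1, points.shape[1])
    pca = PCA(n_components=max_k, svd_solver="full")
    pca.fit(points)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = min(int(np.searchsorted(cum, variance_target) + 1), max_k)
    return pca.components_[:k], float(cum[k - 1])


def mahalanobis_in_basis(
    reference: np.ndarray,
    components: np.ndarray,
    ridge: float = 1e-8,
) -> PCAMahalanobis:
    """Mahalanobis metric of a reference cloud inside an external basis.

    The covariance of the reference is estimated after projecting onto
    ``components`` (fitted elsewhere, e.g. on the whole screen), so the
    basis reflects where treatments vary rather than where this
    particular reference cloud happens to spread.
    """
    reference = np.asarray(reference, dtype=float)
    mean = reference.mean(axis=0)
    projected = (reference - mean) @ components.T
    k = components.shape[0]
    cov = np.atleast_2d(np.cov(projected, rowvar=False)) + ridge * np.eye(k)
    return PCAMahalanobis(
        mean=mean,
        components=components,
        precision=np.linalg.inv(cov),
        n_components=k,
        explained_variance=float("nan"),
    )
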