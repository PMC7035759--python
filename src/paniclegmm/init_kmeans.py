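"""k-means initialization for the Gibbs sampler, and the k-means baseline.

The sampler starts from a k-means++ partition of the pixels: initial weights
are the cluster frequencies n_j / n, initial means the within-cluster sample
means, and initial precisions the inverses of the within-cluster maximum
likelihood covariances.  The same clustering doubles as the classical
unsupervised baseline segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .model_core import PixelMatrix

__all__ = ["InitState", "kmeans_init", "kmeans_segment"]

# Beyond this condition number a scatter matrix is treated as singular.
_COND_MAX = 1e12


@dataclass
class InitState:
    """Initial sampler state derived from a k-means partition."""

    z0: np.ndarray            # (n,) labels in {1, ..., k}
    q0: np.ndarray            # (k,) cluster frequencies n_j / n
    mu0: np.ndarray           # (k, p) cluster means
    phi0: np.ndarray          # (k, p, p) inverse ML covariances
    cluster_sizes: np.ndarray  # (k,) counts n_j

    @property
    def k(self) -> int:
        return self.q0.shape[0]


def _pixel_data(X: PixelMatrix | np.ndarray) -> np.ndarray:
    return X.data if isinstance(X, PixelMatrix) else np.asarray(X, dtype=float)


def _fit_kmeans(data: np.ndarray, k: int, seed: int,
                n_restarts: int) -> np.ndarray:
    if k < 1:
        raise ValueError("k must be >= 1")
    if data.shape[0] < k:
        raise ValueError(f"need at least k={k} pixels, got {data.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
    )
    return km.fit_predict(data) + 1  # 1-based labels


def kmeans_init(X: PixelMatrix | np.ndarray, k: int, seed: int, *,
                n_restarts: int = 3, ridge: float = 1e-6) -> InitState:
    """Cluster pixels with k-means++ and estimate per-cluster ML parameters.

    Parameters
    ----------
    X : PixelMatrix or (n, p) array
    k : number of clusters (>= 2 for mixture initialization)
    seed : RNG seed for the k-means++ restarts
    n_restarts : restarts kept at the lowest within-cluster sum of squares
    ridge : added to a cluster scatter (as ridge * I) when it is singular or
        numerically ill-conditioned; with ridge=0 such a cluster raises.
    """
    data = _pixel_data(X)
    n, p = data.shape
    if k < 2:
        raise ValueError("mixture initialization needs k >= 2")
    z0 = _fit_kmeans(data, k, seed, n_restarts)

    sizes = np.bincount(z0 - 1, minlength=k)
    q0 = sizes / n
    mu0 = np.zeros((k, p))
    phi0 = np.zeros((k, p, p))
    for j in range(k):
        members = data[z0 == j + 1]
        n_j = members.shape[0]
        if n_j == 0:
            # duplicate-heavy data can leave a cluster empty; park it at
            # the global mean with a ridge covariance
            if ridge <= 0:
                raise np.linalg.LinAlgError(
                    f"cluster {j + 1} is empty and ridge is 0"
                )
            mu0[j] = data.mean(axis=0)
            phi0[j] = np.eye(p) / ridge
            continue
        mu0[j] = members.mean(axis=0)
        d = members - mu0[j]
        cov = (d.T @ d) / n_j  # ML covariance (divide by n_j)
        with np.errstate(divide="ignore", invalid="ignore"):
            degenerate = (n_j < p + 1
                          or not np.linalg.cond(cov) <= _COND_MAX)
        if degenerate:
            if ridge <= 0:
                raise np.linalg.LinAlgError(
                    f"cluster {j + 1} has a singular scatter matrix "
                    f"({n_j} members, p={p}) and ridge is 0"
                )
            cov = cov + ridge * np.eye(p)
        phi0[j] = np.linalg.inv(cov)
        phi0[j] = 0.5 * (phi0[j] + phi0[j].T)  # enforce exact symmetry
    return InitState(z0=z0, q0=q0, mu0=mu0, phi0=phi0, cluster_sizes=sizes)


def kmeans_segment(X: PixelMatrix | np.ndarray, k: int, seed: int, *,
                   n_restarts: int = 3) -> np.ndarray:
    """Hard k-means labels (1-based) — the baseline segmenter.

    The panicle cluster is identified downstream by total channel mean,
    exactly as for the Bayesian segmenter.
    """
    return _fit_kmeans(_pixel_data(X), k, seed, n_restarts)
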