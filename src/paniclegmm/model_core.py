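"""Core data containers and density evaluations for the pixel mixture model.

Each pixel of a canopy image is a p-vector of channel intensities in [0, 1]
(p = 3 for RGB).  Pixels are modelled as i.i.d. draws from a k-component
multivariate Gaussian mixture whose components correspond to scene
categories (panicle, leaves, dark background, optional anomaly objects).
Components are parameterized by their mean vector and *precision* matrix
(the inverse covariance): working with precisions avoids a matrix inversion
in every density evaluation and every Gibbs sweep.

All densities are evaluated in log space; mixtures use log-sum-exp.  The
posterior threshold used downstream sits deep in the tail (0.9990), so tail
accuracy matters.

Component indices are 1-based throughout the package, matching the usual
statistical notation j in {1, ..., k}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PixelMatrix",
    "Priors",
    "MixtureState",
    "RunConfig",
    "gaussian_logpdf",
    "gaussian_logpdf_matrix",
    "mixture_logpdf",
    "total_channel_mean",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _check_precision(phi: np.ndarray, name: str = "phi") -> np.ndarray:
    """Validate symmetry/positive-definiteness; return the Cholesky factor."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {phi.shape}")
    if not np.allclose(phi, phi.T, rtol=1e-8, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        return np.linalg.cholesky(phi)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc


@dataclass
class PixelMatrix:
    """An image flattened to an n x p matrix of channel intensities in [0, 1].

    Pixels are flattened row-major from the top-left corner, so
    ``data[row * width + col]`` is the pixel at image coordinate
    (row, col) and ``labels.reshape(height, width)`` restores a 2-D map.
    """

    data: np.ndarray
    height: int
    width: int
    channel_names: tuple[str, ...] = ("red", "green", "blue")

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n pixels x p channels)")
        n, p = self.data.shape
        if self.height * self.width != n:
            raise ValueError(
                f"height*width = {self.height * self.width} != n = {n}"
            )
        if p < 1 or len(self.channel_names) != p:
            raise ValueError("channel_names must match the number of channels")
        if self.data.size and (self.data.min() < 0.0 or self.data.max() > 1.0):
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def to_image(self) -> np.ndarray:
        """Reshape back to (height, width, p)."""
        return self.data.reshape(self.height, self.width, self.n_channels)


@dataclass
class Priors:
    """Conjugate priors for one image's mixture parameters.

    alpha  -- Dirichlet concentration over the k mixing weights.
    tau    -- k prior mean vectors for the component means.
    omega  -- k prior precision matrices for the component means.
    The component precision matrices carry the standard non-informative
    (improper) prior, so their full conditional is Wishart with the
    component's pixel count as degrees of freedom.
    """

    alpha: np.ndarray
    tau: np.ndarray
    omega: np.ndarray
    precision_prior: str = "non-informative"

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.alpha.ndim != 1 or np.any(self.alpha <= 0):
            raise ValueError("alpha must be a 1-D vector of positive entries")
        k = self.alpha.shape[0]
        if self.tau.shape[0] != k or self.omega.shape[0] != k:
            raise ValueError("tau and omega must have one entry per component")
        for j in range(k):
            _check_precision(self.omega[j], name=f"omega[{j + 1}]")

    @classmethod
    def default(cls, k: int, p: int = 3, *, alpha: float = 1.0,
                omega_scale: float = 1e-3) -> "Priors":
        """Weak defaults: flat Dirichlet(1), zero prior mean, precision 1e-3 I."""
        return cls(
            alpha=np.full(k, alpha),
            tau=np.zeros((k, p)),
            omega=np.tile(omega_scale * np.eye(p), (k, 1, 1)),
        )

    @property
    def k(self) -> int:
        return self.alpha.shape[0]


@dataclass
class MixtureState:
    """One state of the sampler: weights, component parameters, and labels."""

    q: np.ndarray
    mu: np.ndarray
    phi: np.ndarray
    z: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.z = np.asarray(self.z, dtype=np.int64)

    @property
    def k(self) -> int:
        return self.q.shape[0]

    def validate(self) -> None:
        """Full invariant check (used in tests; too costly per sweep)."""
        if abs(self.q.sum() - 1.0) > 1e-10 or np.any(self.q < 0):
            raise ValueError("q must be a probability vector")
        for j in range(self.k):
            _check_precision(self.phi[j], name=f"phi[{j + 1}]")
        if self.z.size and (self.z.min() < 1 or self.z.max() > self.k):
            raise ValueError("labels must lie in {1, ..., k}")


@dataclass
class RunConfig:
    """Sampler and pipeline settings.

    n_iter (T) and burn_in (T0) follow the convention that iterations
    burn_in..n_iter inclusive are retained, i.e. the first T0 - 1 samples are
    discarded and T - T0 + 1 are averaged.  p_th is the panicle posterior
    threshold; eps_m / eps_a the cluster-merge and anomaly thresholds; ridge
    regularizes degenerate scatter matrices.
    """

    k: int = 3
    n_iter: int = 150
    burn_in: int = 75
    p_th: float = 0.9990
    eps_m: float = 0.1
    eps_a: float = 0.9
    seed: int = 0
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.burn_in <= self.n_iter:
            raise ValueError(
                f"burn_in must satisfy 1 <= burn_in <= n_iter "
                f"(got burn_in={self.burn_in}, n_iter={self.n_iter})"
            )
        if not 0.0 <= self.p_th <= 1.0:
            raise ValueError("p_th must lie in [0, 1]")
        if self.eps_m < 0 or self.eps_a < 0 or self.ridge < 0:
            raise ValueError("eps_m, eps_a and ridge must be non-negative")

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.burn_in + 1


def gaussian_logpdf(x: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> float:
    """Log density of N_p(mu, phi^{-1}) at x, in the precision parameterization.

    Uses the Cholesky factor of phi for both the log-determinant and the
    quadratic form, so phi is never inverted.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    L = _check_precision(phi)
    p = mu.shape[0]
    d = x - mu
    # (x-mu)' phi (x-mu) = || L' (x-mu) ||^2
    w = L.T @ d
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * p * _LOG_2PI + 0.5 * logdet - 0.5 * (w @ w))


def gaussian_logpdf_matrix(X: np.ndarray, mu: np.ndarray,
                           phi: np.ndarray) -> np.ndarray:
    """Vectorized log densities: X is (n, p), mu (k, p), phi (k, p, p).

    Returns an (n, k) matrix of per-pixel per-component log densities.
    """
    X = np.asarray(X, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n, p = X.shape
    k = mu.shape[0]
    out = np.empty((n, k))
    for j in range(k):
        L = _check_precision(phi[j], name=f"phi[{j + 1}]")
        d = X - mu[j]
        w = d @ L  # rows are L' (x - mu)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, j] = -0.5 * p * _LOG_2PI + 0.5 * logdet - 0.5 * np.einsum(
            "ij,ij->i", w, w
        )
    return out


def mixture_logpdf(x: np.ndarray, state: MixtureState) -> float:
    """Log density of the mixture sum_j q_j N_p(x; mu_j, phi_j^{-1}).

    Computed by log-sum-exp so well-separated components cannot underflow.
    """
    if state.k == 0:
        raise ValueError("mixture must have at least one component")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    logphi = gaussian_logpdf_matrix(x, state.mu, state.phi)[0]
    with np.errstate(divide="ignore"):
        logq = np.log(state.q)
    return float(logsumexp(logq + logphi))


def total_channel_mean(mu: np.ndarray) -> np.ndarray | float:
    """Sum of a component mean across channels, m_i = sum_j mu_ij.

    The scene statistic that orders components: panicle pixels are the
    brightest canopy class, so the panicle component maximizes m, and
    anomaly objects (e.g. white field markers) exceed the anomaly
    threshold.  Accepts a single mean vector or a stack of k of them.
    """
    mu = np.asarray(mu, dtype=float)
    s = mu.sum(axis=-1)
    return float(s) if s.ndim == 0 else s
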