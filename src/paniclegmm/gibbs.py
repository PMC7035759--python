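"""Gibbs sampler for the Bayesian Gaussian mixture over image pixels.

One sweep draws, in a fixed order,

    q | z                  ~ Dirichlet(alpha + n)
    for each component j:
        Phi_j | mu_j, X_j  ~ Wishart_p(S_j^{-1}, n_j)
        mu_j  | Phi_j, X_j ~ N_p(tau_j*, (n_j Phi_j + Omega_j)^{-1})
    z | q, mu, Phi         ~ per-pixel categorical, prob ∝ q_j N_p(x; mu_j, Phi_j^{-1})

where n_j and S_j = sum_{z_i=j} (x_i - mu_j)(x_i - mu_j)^T are the component
counts and scatter matrices, and tau_j* is the precision-weighted blend of
the sample mean and the prior mean.  All draws consume a single numpy
Generator in this documented order, so a seed pins the whole chain.

Mixture components are exchangeable a priori, so chains label-switch.  At
every retained iteration (burn_in..n_iter inclusive) the state is relabeled
so that total channel means are non-increasing in j — the panicle component
is always component 1 — before per-pixel label indicators are accumulated.
The indicator averages over retained sweeps estimate the posterior class
probabilities Pr(z_i = j | X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .init_kmeans import InitState
from .model_core import (
    MixtureState,
    PixelMatrix,
    Priors,
    RunConfig,
    gaussian_logpdf_matrix,
    total_channel_mean,
)

__all__ = [
    "SufficientStats",
    "ChainTrace",
    "sample_q",
    "sample_precision",
    "sample_mean",
    "sample_labels",
    "run_chain",
    "posterior_probabilities",
]


class EmptyComponentError(ValueError):
    """Raised when a precision draw is requested for an empty component."""


@dataclass
class SufficientStats:
    """Per-component counts, sample means, and scatter matrices about mu_j."""

    counts: np.ndarray    # (k,) n_j, summing to n
    means: np.ndarray     # (k, p) x̄_j (zero rows for empty components)
    scatters: np.ndarray  # (k, p, p) S_j = sum (x_i - mu_j)(x_i - mu_j)^T


@dataclass
class ChainTrace:
    """Output of a Gibbs run: indicator counts and post-burn-in summaries."""

    posterior_counts: np.ndarray  # (n, k) integer indicator sums
    n_iter: int
    burn_in: int
    n_retained: int
    q_mean: np.ndarray            # (k,) post-burn-in average weights
    mu_mean: np.ndarray           # (k, p) post-burn-in average means
    phi_mean: np.ndarray          # (k, p, p) post-burn-in average precisions
    final_state: MixtureState
    states: list[MixtureState] | None = None


def sample_q(z: np.ndarray, alpha: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One draw of the mixing weights from Dirichlet(alpha + n).

    Empty components are legal: their mass comes from alpha alone.
    """
    alpha = np.asarray(alpha, dtype=float)
    k = alpha.shape[0]
    counts = np.bincount(np.asarray(z, dtype=np.int64) - 1, minlength=k)
    return rng.dirichlet(alpha + counts)


def sample_precision(S: np.ndarray, n_j: int, ridge: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One Wishart_p(S^{-1}, n_j) draw via the Bartlett construction.

    A factor U with U U' = S^{-1} is obtained from the Cholesky factor of S
    by triangular solve (S itself is never inverted).  When n_j < p the
    Wishart is singular and cannot serve as a precision; the draw is then
    taken with max(n_j, p) degrees of freedom on the ridged scatter.
    Singular scatters are ridged likewise.
    """
    if n_j == 0:
        raise EmptyComponentError("cannot draw a precision for an empty component")
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    df = n_j
    if n_j < p:
        S = S + ridge * np.eye(p)
        df = p
    try:
        C = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        C = np.linalg.cholesky(S + ridge * np.eye(p))
    # U = C^{-T}; then U U' = S^{-1}
    U = solve_triangular(C, np.eye(p), lower=True).T
    # Bartlett: A lower-triangular, A_ii^2 ~ chi2(df - i), A_ij ~ N(0,1)
    A = np.zeros((p, p))
    df_diag = df - np.arange(p)
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df_diag))
    if p > 1:
        A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    M = U @ A
    W = M @ M.T
    return 0.5 * (W + W.T)


def sample_mean(phi: np.ndarray, xbar: np.ndarray, n_j: int, tau: np.ndarray,
                omega: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw of a component mean from its Gaussian full conditional.

    Posterior precision  Omega* = n_j Phi + Omega and posterior mean
    tau* = Omega*^{-1} (n_j Phi x̄ + Omega tau); with n_j = 0 this is a
    draw from the prior.  The draw is tau* + L^{-T} eps with L the
    Cholesky factor of Omega* and eps standard normal.
    """
    phi = np.asarray(phi, dtype=float)
    omega = np.asarray(omega, dtype=float)
    p = omega.shape[0]
    omega_star = n_j * phi + omega
    b = n_j * (phi @ np.asarray(xbar, dtype=float)) + omega @ np.asarray(
        tau, dtype=float
    )
    L = np.linalg.cholesky(omega_star)
    # tau* solves Omega* tau* = b
    y = solve_triangular(L, b, lower=True)
    tau_star = solve_triangular(L.T, y, lower=False)
    eps = rng.standard_normal(p)
    return tau_star + solve_triangular(L.T, eps, lower=False)


def label_probabilities(X: np.ndarray, q: np.ndarray, mu: np.ndarray,
                        phi: np.ndarray) -> np.ndarray:
    """Per-pixel posterior class probabilities at fixed parameters.

    Rows are prob(z_i = j) ∝ q_j N_p(x_i; mu_j, Phi_j^{-1}), normalized in
    log space so no pixel can underflow to an all-zero row.
    """
    logp = gaussian_logpdf_matrix(X, mu, phi)
    with np.errstate(divide="ignore"):
        logp = logp + np.log(np.asarray(q, dtype=float))
    logp -= logsumexp(logp, axis=1, keepdims=True)
    return np.exp(logp)


def _suff_stats(X: np.ndarray, z: np.ndarray, mu: np.ndarray) -> SufficientStats:
    k, p = mu.shape
    counts = np.bincount(z - 1, minlength=k)
    means = np.zeros((k, p))
    scatters = np.zeros((k, p, p))
    for j in range(k):
        members = X[z == j + 1]
        if members.shape[0]:
            means[j] = members.mean(axis=0)
            d = members - mu[j]
            scatters[j] = d.T @ d
    return SufficientStats(counts=counts, means=means, scatters=scatters)


def sample_labels(X: PixelMatrix | np.ndarray, q: np.ndarray, mu: np.ndarray,
                  phi: np.ndarray, rng: np.random.Generator
                  ) -> tuple[np.ndarray, SufficientStats]:
    """Draw every pixel label from its categorical full conditional.

    Returns the new 1-based labels and the sufficient statistics recomputed
    for them (scatters taken about the current mu).
    """
    data = X.data if isinstance(X, PixelMatrix) else np.asarray(X, dtype=float)
    probs = label_probabilities(data, q, mu, phi)
    u = rng.random(data.shape[0])
    z = 1 + np.sum(probs.cumsum(axis=1) < u[:, None], axis=1)
    z = np.minimum(z, mu.shape[0]).astype(np.int64)  # guard roundoff at 1.0
    return z, _suff_stats(data, z, np.asarray(mu, dtype=float))


def _relabel_by_total_mean(q, mu, phi, z):
    """Permute components into non-increasing total-channel-mean order."""
    order = np.argsort(-total_channel_mean(mu), kind="stable")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(order.shape[0])
    return q[order], mu[order], phi[order], inverse[z - 1] + 1


def run_chain(X: PixelMatrix | np.ndarray, init: InitState, priors: Priors,
              config: RunConfig, *, update_parameters: bool = True,
              store_states: bool = False) -> ChainTrace:
    """Run the Gibbs sampler for n_iter sweeps and accumulate indicators.

    Iterations burn_in..n_iter inclusive are retained (n_iter - burn_in + 1
    samples); before each retained iteration's indicators are accumulated
    the state is relabeled into total-channel-mean order.

    With ``update_parameters=False`` the chain holds (q, mu, phi) fixed at
    the initial state and only resamples labels — then the indicator
    averages estimate the closed-form per-pixel categorical probabilities,
    which is used for validation.  No relabeling is applied in that mode
    (fixed, distinct parameters cannot label-switch).
    """
    data = X.data if isinstance(X, PixelMatrix) else np.asarray(X, dtype=float)
    n, p = data.shape
    k = config.k
    if init.k != k or priors.k != k:
        raise ValueError("init, priors and config disagree on k")
    rng = np.random.default_rng(config.seed)

    q = init.q0.copy()
    mu = init.mu0.copy()
    phi = init.phi0.copy()
    z = init.z0.copy()

    posterior_counts = np.zeros((n, k), dtype=np.int64)
    q_sum = np.zeros(k)
    mu_sum = np.zeros((k, p))
    phi_sum = np.zeros((k, p, p))
    states: list[MixtureState] | None = [] if store_states else None
    rows = np.arange(n)

    for itr in range(1, config.n_iter + 1):
        try:
            if update_parameters:
                q = sample_q(z, priors.alpha, rng)
                counts = np.bincount(z - 1, minlength=k)
                for j in range(k):
                    members = data[z == j + 1]
                    n_j = int(counts[j])
                    if n_j == 0:
                        # keep previous Phi_j; mean reverts to its prior
                        mu[j] = sample_mean(
                            phi[j], np.zeros(p), 0, priors.tau[j],
                            priors.omega[j], rng,
                        )
                        continue
                    d = members - mu[j]
                    S = d.T @ d
                    phi[j] = sample_precision(S, n_j, config.ridge, rng)
                    mu[j] = sample_mean(
                        phi[j], members.mean(axis=0), n_j, priors.tau[j],
                        priors.omega[j], rng,
                    )
            z, _ = sample_labels(data, q, mu, phi, rng)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"Gibbs sweep {itr} failed: {exc}") from exc

        if itr >= config.burn_in:
            if update_parameters:
                q, mu, phi, z = _relabel_by_total_mean(q, mu, phi, z)
            posterior_counts[rows, z - 1] += 1
            q_sum += q
            mu_sum += mu
            phi_sum += phi
            if states is not None:
                states.append(
                    MixtureState(q=q.copy(), mu=mu.copy(), phi=phi.copy(),
                                 z=z.copy(), iteration=itr)
                )

    n_ret = config.n_retained
    return ChainTrace(
        posterior_counts=posterior_counts,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        n_retained=n_ret,
        q_mean=q_sum / n_ret,
        mu_mean=mu_sum / n_ret,
        phi_mean=phi_sum / n_ret,
        final_state=MixtureState(q=q, mu=mu, phi=phi, z=z,
                                 iteration=config.n_iter),
        states=states,
    )


def posterior_probabilities(trace: ChainTrace) -> np.ndarray:
    """Posterior class probabilities: indicator counts / retained sweeps."""
    return trace.posterior_counts / trace.n_retained
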