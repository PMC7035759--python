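"""The four full-conditional samplers and the assembled chain."""

import numpy as np
import pytest
from scipy import stats

from paniclegmm import (InitState, Priors, RunConfig, posterior_probabilities,
                        run_chain, sample_labels, sample_mean,
                        sample_precision, sample_q, total_channel_mean)
from paniclegmm.gibbs import EmptyComponentError, label_probabilities

from conftest import best_permutation_mean_error, separated_class_params


class TestSampleQ:
    def test_flat_prior_empirical_mean(self):
        rng = np.random.default_rng(0)
        z = np.array([], dtype=int)
        alpha = np.ones(3)
        draws = np.array([sample_q(z, alpha, rng) for _ in range(10000)])
        np.testing.assert_allclose(draws.mean(axis=0), 1 / 3, atol=0.01)

    def test_posterior_mean_with_counts(self):
        # oracle: Dirichlet mean (alpha_j + n_j) / sum
        rng = np.random.default_rng(1)
        z = np.ones(98, dtype=int)
        alpha = np.ones(2)
        draws = np.array([sample_q(z, alpha, rng) for _ in range(10000)])
        assert draws[:, 0].mean() == pytest.approx(99 / 100, abs=0.01)

    def test_simplex_membership(self):
        rng = np.random.default_rng(2)
        z = np.array([1, 1, 2, 3, 3, 3])
        for _ in range(100):
            q = sample_q(z, np.ones(3), rng)
            assert q.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(q >= 0)

    def test_empty_components_receive_prior_mass(self):
        rng = np.random.default_rng(3)
        z = np.full(50, 1, dtype=int)  # components 2, 3 empty
        draws = np.array([sample_q(z, np.ones(3), rng) for _ in range(5000)])
        # Dirichlet(51, 1, 1) means are (51, 1, 1)/53
        np.testing.assert_allclose(draws.mean(axis=0),
                                   np.array([51, 1, 1]) / 53, atol=0.01)


class TestSamplePrecision:
    def test_empirical_mean_matches_wishart_mean(self, random_precision):
        # oracle: E[W(S^{-1}, df)] = df * S^{-1}
        S = random_precision(3, seed=0) * 0.1
        n_j, n_draws = 50, 20000
        rng = np.random.default_rng(4)
        draws = np.array([sample_precision(S, n_j, 0.0, rng)
                          for _ in range(n_draws)])
        expected = n_j * np.linalg.inv(S)
        # entrywise MC standard error of a Wishart: sd/sqrt(n_draws)
        sd = np.std(draws, axis=0, ddof=1)
        err = np.abs(draws.mean(axis=0) - expected)
        assert np.all(err <= 3 * sd / np.sqrt(n_draws))

    def test_draws_are_positive_definite(self, random_precision):
        rng = np.random.default_rng(5)
        S = random_precision(3, seed=1)
        for _ in range(200):
            np.linalg.cholesky(sample_precision(S, 10, 0.0, rng))

    def test_p1_reduces_to_scaled_chi_square(self):
        # oracle: phi ~ chi2(m) / s for scale 1/s, df m
        rng = np.random.default_rng(6)
        s, m = 2.5, 12
        draws = np.array([sample_precision(np.array([[s]]), m, 0.0, rng)[0, 0]
                          for _ in range(10000)])
        _, pval = stats.kstest(draws * s, stats.chi2(m).cdf)
        assert pval > 0.01

    def test_empty_component_signalled(self):
        rng = np.random.default_rng(7)
        with pytest.raises(EmptyComponentError):
            sample_precision(np.eye(3), 0, 1e-6, rng)

    def test_low_count_ridge_path_stays_positive_definite(self):
        rng = np.random.default_rng(8)
        # n_j < p: rank-deficient scatter must be ridged, draw still PD
        x = np.array([0.3, 0.2, 0.1])
        S = np.outer(x, x)
        draw = sample_precision(S, 1, 1e-6, rng)
        np.linalg.cholesky(draw)


class TestSampleMean:
    def test_no_data_limit_draws_from_prior(self):
        rng = np.random.default_rng(9)
        tau = np.array([0.5, -0.2, 0.1])
        omega = 4.0 * np.eye(3)  # prior sd 0.5
        draws = np.array([
            sample_mean(np.eye(3), np.zeros(3), 0, tau, omega, rng)
            for _ in range(20000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), tau, atol=0.02)
        np.testing.assert_allclose(np.cov(draws.T), np.linalg.inv(omega),
                                   atol=0.01)

    def test_data_dominates_weak_prior(self):
        # oracle: closed-form tau*; with n=1e4 and Omega=1e-3 I the
        # posterior mean sits within 1e-3 of the sample mean
        rng = np.random.default_rng(10)
        xbar = np.array([0.4, 0.5, 0.6])
        omega = 1e-3 * np.eye(3)
        n_j = 10**4
        omega_star = n_j * np.eye(3) + omega
        tau_star = np.linalg.solve(omega_star, n_j * xbar)
        assert np.all(np.abs(tau_star - xbar) < 1e-3)
        draws = np.array([
            sample_mean(np.eye(3), xbar, n_j, np.zeros(3), omega, rng)
            for _ in range(5000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), tau_star, atol=1e-3)

    def test_draw_covariance_is_inverse_posterior_precision(self,
                                                            random_precision):
        # oracle: matrix inverse of the constructed precision
        rng = np.random.default_rng(11)
        phi = random_precision(3, seed=2)
        omega = random_precision(3, seed=3)
        n_j = 7
        xbar = np.array([0.2, 0.3, 0.1])
        draws = np.array([
            sample_mean(phi, xbar, n_j, np.zeros(3), omega, rng)
            for _ in range(20000)
        ])
        expected_cov = np.linalg.inv(n_j * phi + omega)
        np.testing.assert_allclose(np.cov(draws.T), expected_cov,
                                   atol=5e-3)


class TestSampleLabels:
    def test_identical_components_symmetric(self):
        rng = np.random.default_rng(12)
        X = np.full((10000, 3), 0.5)
        mu = np.tile([0.5, 0.5, 0.5], (2, 1))
        phi = np.tile(np.eye(3), (2, 1, 1))
        z, stats_ = sample_labels(X, np.array([0.5, 0.5]), mu, phi, rng)
        assert np.mean(z == 1) == pytest.approx(0.5, abs=0.01)
        assert stats_.counts.sum() == 10000

    def test_degenerate_weights_deterministic(self):
        rng = np.random.default_rng(13)
        X = np.random.default_rng(0).random((100, 3))
        mu = np.tile([0.5, 0.5, 0.5], (2, 1))
        phi = np.tile(np.eye(3), (2, 1, 1))
        z, _ = sample_labels(X, np.array([1.0, 0.0]), mu, phi, rng)
        assert np.all(z == 1)

    def test_frequencies_match_closed_form(self, random_precision):
        # oracle: direct evaluation of the categorical full conditional
        rng = np.random.default_rng(14)
        x = np.array([[0.35, 0.4, 0.3]])
        mu = np.array([[0.3, 0.4, 0.3], [0.5, 0.5, 0.4], [0.1, 0.1, 0.1]])
        phi = np.stack([random_precision(3, s) * 50 for s in (1, 2, 3)])
        q = np.array([0.3, 0.45, 0.25])
        probs = label_probabilities(x, q, mu, phi)[0]
        n_draws = 50000
        counts = np.zeros(3)
        for _ in range(n_draws):
            z, _ = sample_labels(x, q, mu, phi, rng)
            counts[z[0] - 1] += 1
        freq = counts / n_draws
        se = np.sqrt(probs * (1 - probs) / n_draws)
        assert np.all(np.abs(freq - probs) <= 3 * se + 1e-12)

    def test_label_probability_rows_normalized(self, random_precision):
        rng = np.random.default_rng(15)
        X = rng.random((50, 3))
        mu = rng.random((3, 3))
        phi = np.stack([random_precision(3, s) for s in (4, 5, 6)])
        P = label_probabilities(X, np.array([0.2, 0.3, 0.5]), mu, phi)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_scatter_definition(self):
        rng = np.random.default_rng(16)
        X = rng.random((20, 3))
        mu = np.array([[0.2, 0.2, 0.2], [0.8, 0.8, 0.8]])
        phi = np.tile(50 * np.eye(3), (2, 1, 1))
        z, st_ = sample_labels(X, np.array([0.5, 0.5]), mu, phi, rng)
        for j in (1, 2):
            members = X[z == j]
            d = members - mu[j - 1]
            np.testing.assert_allclose(st_.scatters[j - 1], d.T @ d,
                                       atol=1e-12)


def _single_component_problem(n=400, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal([0.4, 0.5, 0.3], 0.05, size=(n, 3)).clip(0, 1)
    mu0 = data.mean(axis=0)
    d = data - mu0
    phi0 = np.linalg.inv(d.T @ d / n)
    init = InitState(z0=np.ones(n, dtype=int), q0=np.array([1.0]),
                     mu0=mu0[None], phi0=phi0[None],
                     cluster_sizes=np.array([n]))
    priors = Priors.default(1)
    return data, init, priors


class TestRunChain:
    def test_single_component_posterior_counts_full(self):
        data, init, priors = _single_component_problem()
        cfg = RunConfig(k=1, n_iter=60, burn_in=30, seed=0)
        trace = run_chain(data, init, priors, cfg)
        np.testing.assert_array_equal(trace.posterior_counts[:, 0],
                                      cfg.n_retained)

    def test_single_component_mean_matches_conjugate_posterior(self):
        # oracle: analytic tau* of the Gaussian full conditional; with a
        # weak prior the posterior mean is within MC error of the sample
        # mean
        data, init, priors = _single_component_problem(n=500, seed=1)
        cfg = RunConfig(k=1, n_iter=300, burn_in=100, seed=1)
        trace = run_chain(data, init, priors, cfg, store_states=True)
        mu_draws = np.array([s.mu[0] for s in trace.states])
        n = data.shape[0]
        xbar = data.mean(axis=0)
        phi_hat = trace.phi_mean[0]
        omega_star = n * phi_hat + priors.omega[0]
        tau_star = np.linalg.solve(omega_star, n * phi_hat @ xbar)
        se = mu_draws.std(axis=0, ddof=1) / np.sqrt(mu_draws.shape[0])
        assert np.all(np.abs(mu_draws.mean(axis=0) - tau_star) <= 3 * se)

    def test_frozen_parameters_match_closed_form(self, random_precision):
        # oracle: the per-pixel categorical probabilities at the frozen
        # parameters
        rng = np.random.default_rng(17)
        n, k = 20, 3
        X = rng.random((n, 3))
        mu = np.array([[0.7, 0.7, 0.6], [0.4, 0.45, 0.35], [0.1, 0.1, 0.1]])
        phi = np.stack([random_precision(3, s) * 30 for s in (1, 2, 3)])
        q = np.array([0.2, 0.4, 0.4])
        init = InitState(z0=np.ones(n, dtype=int), q0=q, mu0=mu, phi0=phi,
                         cluster_sizes=np.array([n, 0, 0]))
        cfg = RunConfig(k=3, n_iter=4000, burn_in=1, seed=2)
        trace = run_chain(X, init, Priors.default(3), cfg,
                          update_parameters=False)
        est = posterior_probabilities(trace)
        expected = label_probabilities(X, q, mu, phi)
        se = np.sqrt(expected * (1 - expected) / cfg.n_retained)
        assert np.all(np.abs(est - expected) <= 3 * se + 1e-9)

    def test_same_seed_bit_identical(self, iid_draw):
        pm, _, _ = iid_draw
        from paniclegmm import kmeans_init
        init = kmeans_init(pm, 3, seed=0)
        cfg = RunConfig(k=3, n_iter=30, burn_in=15, seed=5)
        t1 = run_chain(pm, init, Priors.default(3), cfg)
        t2 = run_chain(pm, init, Priors.default(3), cfg)
        np.testing.assert_array_equal(t1.posterior_counts,
                                      t2.posterior_counts)
        np.testing.assert_array_equal(t1.mu_mean, t2.mu_mean)
        np.testing.assert_array_equal(t1.phi_mean, t2.phi_mean)

    def test_retained_components_ordered_by_total_mean(self, iid_draw):
        pm, _, _ = iid_draw
        from paniclegmm import kmeans_init
        init = kmeans_init(pm, 3, seed=0)
        cfg = RunConfig(k=3, n_iter=40, burn_in=20, seed=6)
        trace = run_chain(pm, init, Priors.default(3), cfg, store_states=True)
        for state in trace.states:
            m = total_channel_mean(state.mu)
            assert np.all(np.diff(m) <= 1e-12)

    def test_label_counts_conserved_each_sweep(self, iid_draw):
        pm, _, _ = iid_draw
        from paniclegmm import kmeans_init
        init = kmeans_init(pm, 3, seed=0)
        cfg = RunConfig(k=3, n_iter=30, burn_in=1, seed=7)
        trace = run_chain(pm, init, Priors.default(3), cfg, store_states=True)
        for state in trace.states:
            assert state.z.shape[0] == pm.n_pixels
            assert np.bincount(state.z - 1, minlength=3).sum() == pm.n_pixels
            state.validate()  # q on simplex, phi PD, labels in range

    def test_parameter_recovery_on_iid_mixture(self, iid_draw):
        pm, labels, params = iid_draw
        from paniclegmm import kmeans_init
        from sklearn.metrics import adjusted_rand_score
        init = kmeans_init(pm, 3, seed=0)
        cfg = RunConfig(k=3, n_iter=80, burn_in=40, seed=8)
        trace = run_chain(pm, init, Priors.default(3), cfg)
        truth = np.array([c.mean for c in params])
        assert best_permutation_mean_error(trace.mu_mean, truth) < 0.05
        post = posterior_probabilities(trace)
        map_labels = np.argmax(post, axis=1) + 1
        assert adjusted_rand_score(labels, map_labels) >= 0.95

    def test_stationarity_from_generating_parameters(self):
        # initialize at the truth of a synthetic draw; post-burn-in means
        # must stay within 3 MC standard errors of the generating values
        from paniclegmm import iid_pixels
        params = separated_class_params()
        pm, labels = iid_pixels(params, 4000, seed=20)
        truth_mu = np.array([c.mean for c in params])
        truth_phi = np.stack([np.linalg.inv(c.cov) for c in params])
        q_true = np.array([c.prevalence for c in params])
        init = InitState(z0=labels, q0=q_true, mu0=truth_mu.copy(),
                         phi0=truth_phi.copy(),
                         cluster_sizes=np.bincount(labels - 1, minlength=3))
        cfg = RunConfig(k=3, n_iter=120, burn_in=40, seed=21)
        trace = run_chain(pm, init, Priors.default(3), cfg, store_states=True)
        mu_draws = np.array([s.mu for s in trace.states])
        # components are relabeled brightest-first; reorder truth to match
        order = np.argsort(-truth_mu.sum(axis=1))
        se = mu_draws.std(axis=0, ddof=1) / np.sqrt(len(trace.states))
        err = np.abs(mu_draws.mean(axis=0) - truth_mu[order])
        # allow 3 SEs plus the finite-sample offset of the draw itself,
        # bounded by 3 sigma / sqrt(smallest class count)
        n_min = (q_true * 4000).min()
        assert np.all(err <= 3 * se + 3 * 0.02 / np.sqrt(n_min))


class TestPosteriorProbabilities:
    def test_rows_sum_to_one(self):
        data, init, priors = _single_component_problem(n=50)
        cfg = RunConfig(k=1, n_iter=20, burn_in=10, seed=0)
        post = posterior_probabilities(run_chain(data, init, priors, cfg))
        np.testing.assert_array_equal(post.sum(axis=1), 1.0)

    def test_normalization_is_count_over_retained(self):
        from paniclegmm.gibbs import ChainTrace
        counts = np.array([[75, 0, 0], [38, 37, 0]])
        trace = ChainTrace(
            posterior_counts=counts, n_iter=150, burn_in=76, n_retained=75,
            q_mean=np.ones(3) / 3, mu_mean=np.zeros((3, 3)),
            phi_mean=np.tile(np.eye(3), (3, 1, 1)), final_state=None,
        )
        post = posterior_probabilities(trace)
        np.testing.assert_allclose(post[0], [1, 0, 0])
        np.testing.assert_allclose(post[1], [38 / 75, 37 / 75, 0])
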