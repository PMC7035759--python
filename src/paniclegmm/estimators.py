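"""Scikit-learn style estimators wrapping the full segmentation pipeline.

`GibbsGMMSegmenter` is the unsupervised Bayesian segmenter: fit() runs
k-means initialization, the Gibbs chain, posterior averaging, cluster
merging, anomaly detection and panicle identification on one image's
pixels; fitted attributes expose every intermediate.  `KMeansSegmenter` is
the classical baseline with the same panicle-identification rule.

Both follow the sklearn clusterer contract (fit / fit_predict / labels_,
get_params / set_params), so they compose with sklearn tooling.  Labels
are 1-based with component 1 the brightest (largest total channel mean),
matching the rest of the package.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import classify as _classify
from . import postprocess as _post
from .gibbs import label_probabilities, posterior_probabilities, run_chain
from .init_kmeans import kmeans_init, kmeans_segment
from .model_core import PixelMatrix, Priors, RunConfig, total_channel_mean

__all__ = ["GibbsGMMSegmenter", "KMeansSegmenter"]


def _as_data(X) -> np.ndarray:
    if isinstance(X, PixelMatrix):
        return X.data
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an (n_pixels, n_channels) array")
    return X


class GibbsGMMSegmenter(ClusterMixin, BaseEstimator):
    """Unsupervised Bayesian pixel segmenter via Gibbs-sampled GMM.

    Parameters
    ----------
    k : number of mixture components (scene classes).
    n_iter, burn_in : total Gibbs sweeps T and burn-in T0; iterations
        burn_in..n_iter are retained (T - T0 + 1 samples).
    alpha : Dirichlet concentration on the mixing weights.
    prior_mean : prior mean of every component mean vector.
    prior_precision_scale : omega, the prior precision of the component
        means is omega * I (weak by default, 1e-3).
    p_th : posterior threshold for the panicle mask.
    eps_m : merge clusters whose means are closer than this (Euclidean).
    eps_a : flag merged clusters whose total channel mean reaches this.
    ridge : regularizer for degenerate scatter matrices.
    kmeans_restarts : k-means++ restarts for initialization.
    store_trace : keep the full per-iteration parameter trace (memory).
    random_state : seed for the single RNG stream driving the chain.

    Attributes (after fit)
    ----------------------
    weights_, means_, precisions_ : post-burn-in posterior means of the
        mixture parameters, components ordered by decreasing total
        channel mean.
    posterior_ : (n, k) posterior class probabilities (indicator averages).
    merge_map_, merged_means_, anomaly_flags_ : cluster-merge bookkeeping.
    merged_posterior_ : (n, k') posteriors after merging.
    panicle_component_ : 1-based merged index of the panicle class.
    labels_ : (n,) MAP labels over merged components.
    panicle_mask_ : (n,) thresholded panicle mask at p_th.
    result_ : the SegmentationResult bundle.
    """

    def __init__(self, k: int = 3, n_iter: int = 150, burn_in: int = 75,
                 alpha: float = 1.0, prior_mean: float = 0.0,
                 prior_precision_scale: float = 1e-3, p_th: float = 0.9990,
                 eps_m: float = 0.1, eps_a: float = 0.9, ridge: float = 1e-6,
                 kmeans_restarts: int = 3, store_trace: bool = False,
                 random_state: int | None = None):
        self.k = k
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.alpha = alpha
        self.prior_mean = prior_mean
        self.prior_precision_scale = prior_precision_scale
        self.p_th = p_th
        self.eps_m = eps_m
        self.eps_a = eps_a
        self.ridge = ridge
        self.kmeans_restarts = kmeans_restarts
        self.store_trace = store_trace
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return RunConfig(
            k=self.k, n_iter=self.n_iter, burn_in=self.burn_in,
            p_th=self.p_th, eps_m=self.eps_m, eps_a=self.eps_a,
            seed=0 if self.random_state is None else int(self.random_state),
            ridge=self.ridge,
        )

    def fit(self, X, y=None):
        """Learn the mixture from one image's pixels and segment them."""
        data = _as_data(X)
        n, p = data.shape
        config = self._config()
        priors = Priors(
            alpha=np.full(self.k, float(self.alpha)),
            tau=np.full((self.k, p), float(self.prior_mean)),
            omega=np.tile(self.prior_precision_scale * np.eye(p),
                          (self.k, 1, 1)),
        )
        init = kmeans_init(data, self.k, config.seed,
                           n_restarts=self.kmeans_restarts, ridge=self.ridge)
        trace = run_chain(data, init, priors, config,
                          store_states=self.store_trace)
        self.trace_ = trace
        self.n_retained_ = trace.n_retained
        self.weights_ = trace.q_mean
        self.means_ = trace.mu_mean
        self.precisions_ = trace.phi_mean
        self.posterior_ = posterior_probabilities(trace)

        graph = _post.merge_clusters(self.means_, self.weights_, self.eps_m)
        graph.anomaly_flags = _post.detect_anomalies(graph.component_means,
                                                     self.eps_a)
        self.merge_map_ = graph.merge_map
        self.merged_means_ = graph.component_means
        self.merged_weights_ = graph.component_weights
        self.anomaly_flags_ = graph.anomaly_flags
        self.cluster_graph_ = graph
        self.merged_posterior_ = _post.merge_posteriors(self.posterior_,
                                                        graph.merge_map)

        self.panicle_component_ = _classify.identify_panicle_component(
            graph.component_means, exclude=graph.anomaly_flags
        )
        self.labels_ = _classify.map_classify(self.merged_posterior_)
        self.panicle_mask_ = _classify.threshold_classify(
            self.merged_posterior_, self.panicle_component_, self.p_th
        )
        self.component_total_means_ = np.atleast_1d(
            total_channel_mean(graph.component_means)
        )
        self.result_ = _classify.SegmentationResult(
            map_labels=self.labels_,
            panicle_component=self.panicle_component_,
            panicle_mask=self.panicle_mask_,
            threshold_used=self.p_th,
            component_total_means=self.component_total_means_,
        )
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        """Merged-component posteriors for X (or the fitted pixels).

        For new pixels, probabilities are evaluated at the post-burn-in
        posterior-mean parameters and then summed over merged members.
        """
        if X is None:
            return self.merged_posterior_
        probs = label_probabilities(_as_data(X), self.weights_, self.means_,
                                    self.precisions_)
        return _post.merge_posteriors(probs, self.merge_map_)

    def predict(self, X=None) -> np.ndarray:
        """MAP labels over merged components (1-based)."""
        if X is None:
            return self.labels_
        return _classify.map_classify(self.predict_proba(X))

    def panicle_mask(self, X=None, p_th: float | None = None) -> np.ndarray:
        """Thresholded panicle mask, optionally at a different threshold."""
        proba = self.merged_posterior_ if X is None else self.predict_proba(X)
        th = self.p_th if p_th is None else p_th
        return _classify.threshold_classify(proba, self.panicle_component_,
                                            th)


class KMeansSegmenter(ClusterMixin, BaseEstimator):
    """k-means++ baseline segmenter with total-channel-mean panicle rule.

    ``eps_a`` (optional) excludes bright anomaly clusters before the
    panicle cluster is chosen, mirroring the Bayesian pipeline; by default
    no exclusion is applied.
    """

    def __init__(self, k: int = 3, n_restarts: int = 3,
                 eps_a: float | None = None, random_state: int | None = None):
        self.k = k
        self.n_restarts = n_restarts
        self.eps_a = eps_a
        self.random_state = random_state

    def fit(self, X, y=None):
        data = _as_data(X)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.labels_ = kmeans_segment(data, self.k, seed,
                                      n_restarts=self.n_restarts)
        k = self.k
        self.cluster_means_ = np.vstack([
            data[self.labels_ == j + 1].mean(axis=0) for j in range(k)
        ])
        exclude = None
        if self.eps_a is not None:
            exclude = _post.detect_anomalies(self.cluster_means_, self.eps_a)
        self.anomaly_flags_ = exclude
        self.panicle_component_ = _classify.identify_panicle_component(
            self.cluster_means_, exclude=exclude
        )
        self.panicle_mask_ = self.labels_ == self.panicle_component_
        return self
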