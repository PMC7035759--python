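"""Cluster merging and anomaly detection after classification.

Segmenting with more clusters than scene classes (k > 3) absorbs
illumination variation — a single leaf class can split into lit and
shadowed clusters — and gives anomalous bright objects (field markers)
their own cluster.  Two post-steps repair the cluster set:

1. *Merging*: clusters whose means are closer than eps_m in Euclidean
   distance are merged.  The pairwise rule is closed transitively
   (connected components of the under-threshold graph), so the result does
   not depend on comparison order.  A merged cluster's mean is the
   weight-weighted average of its members' means and its posterior column
   is the sum of theirs, which conserves per-pixel posterior mass.
2. *Anomaly detection*: a merged cluster is flagged anomalous when its
   total channel mean reaches eps_a; flagged clusters are removed from the
   candidate set before the panicle component is identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .model_core import total_channel_mean

__all__ = ["ClusterGraph", "merge_clusters", "detect_anomalies",
           "merge_posteriors"]


@dataclass
class ClusterGraph:
    """Bookkeeping of a merge: k original clusters -> k' merged clusters."""

    component_means: np.ndarray   # (k', p) merged means
    component_weights: np.ndarray  # (k',) summed member weights
    merge_map: np.ndarray         # (k,) original 1-based -> merged 1-based
    anomaly_flags: np.ndarray | None = None  # (k',) booleans, set later

    @property
    def n_merged(self) -> int:
        return self.component_means.shape[0]


def merge_clusters(mu: np.ndarray, weights: np.ndarray,
                   eps_m: float) -> ClusterGraph:
    """Merge clusters whose means are within eps_m, transitively.

    ``weights`` (posterior mass or pixel counts, non-negative and not all
    zero) weight the merged means.  With eps_m = 0 the merge is the
    identity, since the rule is a strict inequality.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if eps_m < 0:
        raise ValueError("eps_m must be non-negative")
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    k = mu.shape[0]

    close = squareform(pdist(mu)) < eps_m if k > 1 else np.ones((1, 1), bool)
    n_comp, groups = connected_components(csr_matrix(close), directed=False)

    means = np.zeros((n_comp, mu.shape[1]))
    wsum = np.zeros(n_comp)
    for g in range(n_comp):
        members = groups == g
        w = weights[members]
        if w.sum() == 0:  # zero-mass group: plain average
            means[g] = mu[members].mean(axis=0)
        else:
            means[g] = (w[:, None] * mu[members]).sum(axis=0) / w.sum()
        wsum[g] = w.sum()

    # order merged clusters by decreasing total channel mean, keeping the
    # package-wide convention that component 1 is the brightest
    order = np.argsort(-total_channel_mean(means), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(n_comp)
    return ClusterGraph(
        component_means=means[order],
        component_weights=wsum[order],
        merge_map=rank[groups] + 1,
    )


def detect_anomalies(component_means: np.ndarray, eps_a: float) -> np.ndarray:
    """Flag clusters whose total channel mean is >= eps_a (inclusive)."""
    if eps_a < 0:
        raise ValueError("eps_a must be non-negative")
    m = np.atleast_1d(total_channel_mean(np.asarray(component_means, float)))
    return m >= eps_a


def merge_posteriors(posteriors: np.ndarray, merge_map: np.ndarray
                     ) -> np.ndarray:
    """Sum posterior columns of merged members; rows keep their total mass."""
    posteriors = np.asarray(posteriors, dtype=float)
    merge_map = np.asarray(merge_map, dtype=np.int64)
    k_merged = int(merge_map.max())
    out = np.zeros((posteriors.shape[0], k_merged))
    for j, g in enumerate(merge_map):
        out[:, g - 1] += posteriors[:, j]
    return out
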