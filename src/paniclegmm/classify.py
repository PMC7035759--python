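"""Turning posterior class probabilities into segmentations.

The panicle component is the one with the largest total channel mean
(panicles are the brightest canopy class).  Two decision rules are
provided: the MAP rule (per-pixel argmax over components) and a
thresholded rule that flags a pixel as panicle only when its panicle
posterior reaches p_th — the knob that trades recall against precision
and traces the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import total_channel_mean

__all__ = [
    "SegmentationResult",
    "identify_panicle_component",
    "map_classify",
    "threshold_classify",
]


@dataclass
class SegmentationResult:
    """Hard labels plus the thresholded panicle mask for one image."""

    map_labels: np.ndarray            # (n,) labels in {1, ..., k}
    panicle_component: int            # 1-based index c
    panicle_mask: np.ndarray          # (n,) booleans
    threshold_used: float
    component_total_means: np.ndarray  # (k,) m_i


def identify_panicle_component(mu: np.ndarray,
                               exclude: np.ndarray | None = None) -> int:
    """Index (1-based) of the component with the largest total channel mean.

    ``exclude`` marks components (e.g. detected anomalies) that may not be
    chosen.  Ties break to the lowest index.
    """
    m = np.atleast_1d(total_channel_mean(np.asarray(mu, dtype=float)))
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.all():
            raise ValueError("no candidate panicle cluster: all components excluded")
        m = np.where(exclude, -np.inf, m)
    return int(np.argmax(m)) + 1


def map_classify(posteriors: np.ndarray) -> np.ndarray:
    """Per-pixel MAP labels (1-based); argmax ties break to the lowest index."""
    posteriors = np.asarray(posteriors, dtype=float)
    return np.argmax(posteriors, axis=1).astype(np.int64) + 1


def threshold_classify(posteriors: np.ndarray, c: int,
                       p_th: float) -> np.ndarray:
    """Panicle mask: pixel flagged iff its component-c posterior >= p_th.

    The comparison is inclusive, so ties at exactly p_th count as panicle.
    """
    if not 0.0 <= p_th <= 1.0:
        raise ValueError("p_th must lie in [0, 1]")
    posteriors = np.asarray(posteriors, dtype=float)
    return posteriors[:, c - 1] >= p_th
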