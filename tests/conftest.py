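import numpy as np
import pytest
from itertools import permutations

from paniclegmm import ClassParams, iid_pixels


def separated_class_params():
    """Three well-separated classes (>= 0.2 per channel between neighbours).

    Ordered panicle, leaf, background; panicle prevalence 6% mirrors the
    low panicle fractions of real heading-stage canopies.
    """
    sd = 0.02
    return [
        ClassParams("panicle", (0.62, 0.60, 0.50), sd ** 2, 0.06),
        ClassParams("leaf", (0.30, 0.40, 0.25), sd ** 2, 0.47),
        ClassParams("background", (0.08, 0.12, 0.05), sd ** 2, 0.47),
    ]


def best_permutation_mean_error(estimated, truth):
    """Max |per-channel| error after the best component matching."""
    estimated = np.asarray(estimated)
    truth = np.asarray(truth)
    k = truth.shape[0]
    best = np.inf
    for perm in permutations(range(k)):
        err = np.abs(estimated[list(perm)] - truth).max()
        best = min(best, err)
    return best


@pytest.fixture(scope="session")
def iid_draw():
    """A 3-class i.i.d. mixture draw with known labels and parameters."""
    params = separated_class_params()
    pm, labels = iid_pixels(params, 3000, seed=7)
    return pm, labels, params


@pytest.fixture
def random_precision():
    """Factory for random symmetric positive-definite precision matrices."""
    def make(p, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((p, p))
        return A @ A.T + np.eye(p)
    return make
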