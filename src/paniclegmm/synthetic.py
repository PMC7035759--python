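"""Synthetic canopy scenes with known pixel labels.

Real aerial canopy images have a small set of intensity classes — bright
panicles over mid-intensity leaves and dark background, occasionally with a
very bright anomalous object such as a white field marker — whose
class-conditional RGB intensities are approximately multivariate Gaussian.
The generator reproduces exactly that statistical structure: it paints
elliptical panicle blobs, background patches and rectangular anomaly
patches over a leaf canvas, then draws every pixel's RGB from its class's
Gaussian, clipped to [0, 1] the way a saturating camera would.

``iid_pixels`` drops the spatial painting and draws labels i.i.d. from the
class prevalences — exactly the generative mixture model the sampler
assumes — for parameter-recovery experiments.

Default class means are chosen so total channel means order as
panicle > leaf > background (the identification rule) with the panicle sum
below the anomaly threshold 0.9, and the anomaly class sum above it.
Default panicle prevalence is 6%, within the 3.7-8.5% range typical of
heading-stage paddy canopies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _ellipse

from .model_core import PixelMatrix

__all__ = ["ClassParams", "SceneSpec", "default_class_params",
           "default_scene_spec", "generate_scene", "iid_pixels"]


@dataclass
class ClassParams:
    """One scene class: its Gaussian color model and spatial footprint."""

    name: str
    mean: np.ndarray              # (3,) channel means in [0, 1]
    cov: np.ndarray               # (3, 3) covariance (scalar = isotropic var)
    prevalence: float
    shape: str = "ellipse"        # "base" | "ellipse" | "panicle" | "rectangle"
    axes: tuple[int, int] = (8, 25)  # blob semi-axis / half-size range, px

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 0:
            cov = float(cov) * np.eye(self.mean.shape[0])
        self.cov = cov
        np.linalg.cholesky(self.cov)  # must be positive definite
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass
class SceneSpec:
    """Layout and color model of one synthetic scene."""

    height: int
    width: int
    class_params: list[ClassParams]
    clip_policy: str = "clip"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        total = sum(c.prevalence for c in self.class_params)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"prevalences must sum to 1, got {total}")
        n_base = sum(c.shape == "base" for c in self.class_params)
        if n_base != 1:
            raise ValueError("exactly one class must have shape='base'")
        if self.clip_policy != "clip":
            raise ValueError("only the 'clip' policy is supported")
        for c in self.class_params:
            if c.shape != "base" and 2 * c.axes[1] > min(self.height,
                                                         self.width):
                raise ValueError(
                    f"blobs of class '{c.name}' exceed the image size"
                )


def default_class_params(*, include_anomaly: bool = False,
                         split_leaf: bool = False,
                         panicle_prevalence: float = 0.06,
                         noise_sd: float = 0.02) -> list[ClassParams]:
    """The default scene classes: leaf canvas, dark background, panicles.

    Optionally adds a white anomaly rectangle class and/or splits the leaf
    class into lit and shadowed variants whose means are < 0.1 apart
    (emulating illumination variation that the merge step must repair).
    """
    var = noise_sd ** 2
    prev_bg = 0.30
    prev_anom = 0.02 if include_anomaly else 0.0
    prev_shadow = 0.20 if split_leaf else 0.0
    prev_leaf = 1.0 - prev_bg - panicle_prevalence - prev_anom - prev_shadow
    params = [
        ClassParams("leaf", (0.10, 0.25, 0.08), var, prev_leaf, shape="base"),
        ClassParams("background", (0.06, 0.08, 0.05), (0.015) ** 2, prev_bg,
                    shape="ellipse", axes=(8, 25)),
        ClassParams("panicle", (0.30, 0.28, 0.22), var, panicle_prevalence,
                    shape="panicle", axes=(2, 5)),
    ]
    if split_leaf:
        params.append(
            ClassParams("leaf_shadow", (0.15, 0.30, 0.13), var, prev_shadow,
                        shape="ellipse", axes=(8, 20))
        )
    if include_anomaly:
        params.append(
            ClassParams("anomaly", (0.85, 0.85, 0.82), var, prev_anom,
                        shape="rectangle", axes=(8, 20))
        )
    return params


def default_scene_spec(height: int = 200, width: int = 200, *, seed: int = 0,
                       **kwargs) -> SceneSpec:
    return SceneSpec(height=height, width=width,
                     class_params=default_class_params(**kwargs), seed=seed)


def _paint_labels(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    base_idx = next(i for i, c in enumerate(spec.class_params)
                    if c.shape == "base")
    labels = np.full((h, w), base_idx + 1, dtype=np.int64)
    for i, cp in enumerate(spec.class_params):
        if cp.shape == "base":
            continue
        target = cp.prevalence * h * w
        lo, hi = cp.axes
        for _ in range(10000):
            if np.count_nonzero(labels == i + 1) >= target:
                break
            r0 = rng.integers(0, h)
            c0 = rng.integers(0, w)
            if cp.shape == "rectangle":
                ar = int(rng.integers(lo, hi + 1))
                ac = int(rng.integers(lo, hi + 1))
                labels[max(0, r0 - ar):min(h, r0 + ar),
                       max(0, c0 - ac):min(w, c0 + ac)] = i + 1
            else:
                a = int(rng.integers(lo, hi + 1))
                if cp.shape == "panicle":  # elongated blobs
                    b = max(1, 3 * a)
                else:
                    b = int(rng.integers(lo, hi + 1))
                rot = rng.uniform(-np.pi / 2, np.pi / 2)
                rr, cc = _ellipse(r0, c0, a, b, shape=(h, w), rotation=rot)
                labels[rr, cc] = i + 1
    return labels.ravel()


def _draw_colors(class_params: list[ClassParams], labels: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Class-conditional Gaussian draws; returns (colors, clipped fraction)."""
    n = labels.shape[0]
    p = class_params[0].mean.shape[0]
    colors = np.empty((n, p))
    for i, cp in enumerate(class_params):
        idx = np.flatnonzero(labels == i + 1)
        L = np.linalg.cholesky(cp.cov)
        colors[idx] = cp.mean + rng.standard_normal((idx.size, p)) @ L.T
    clipped = float(np.mean((colors < 0.0) | (colors > 1.0)))
    return np.clip(colors, 0.0, 1.0), clipped


def generate_scene(spec: SceneSpec, *, return_info: bool = False):
    """Render one scene: returns (PixelMatrix, labels[, info]).

    Labels are 1-based indices into ``spec.class_params``, flattened
    row-major like the pixel matrix.  Deterministic given ``spec.seed``.
    ``info`` (optional) reports the fraction of clipped draws and the
    empirical class prevalences.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _paint_labels(spec, rng)
    colors, clipped = _draw_colors(spec.class_params, labels, rng)
    pm = PixelMatrix(data=colors, height=spec.height, width=spec.width)
    if not return_info:
        return pm, labels
    k = len(spec.class_params)
    info = {
        "clip_fraction": clipped,
        "prevalence": np.bincount(labels - 1, minlength=k) / labels.size,
    }
    return pm, labels, info


def iid_pixels(class_params: list[ClassParams], n: int,
               seed: int) -> tuple[PixelMatrix, np.ndarray]:
    """n i.i.d. mixture draws with known labels — the model's own data.

    This is the exact generative process the sampler assumes (no spatial
    structure), so it is the reference input for parameter recovery.
    Returned as an n x 1 'image'.
    """
    rng = np.random.default_rng(seed)
    prev = np.array([c.prevalence for c in class_params])
    if abs(prev.sum() - 1.0) > 1e-8:
        raise ValueError("prevalences must sum to 1")
    labels = rng.choice(len(class_params), size=n, p=prev) + 1
    colors, _ = _draw_colors(class_params, labels, rng)
    return PixelMatrix(data=colors, height=n, width=1), labels
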