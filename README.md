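# paniclegmm

Unsupervised Bayesian segmentation of rice panicle pixels in canopy images
(e.g. low-altitude aerial photographs of paddy fields), for plant
phenotyping workflows where labelled training data is scarce and imaging
conditions vary from image to image.

Instead of training a supervised model, `paniclegmm` learns the statistical
structure of *each image on its own*. The RGB intensities of the n pixels
x_1, …, x_n (normalized to [0, 1]) are modelled as a k-component
multivariate Gaussian mixture,

    f(x_i) = Σ_j q_j · N_p(x_i; μ_j, Φ_j⁻¹),          j = 1, …, k,

with mixing weights **q** ~ Dirichlet(α), Gaussian priors
μ_j ~ N_p(τ_j, Ω_j⁻¹) on the component means, and the standard
non-informative prior on the precision matrices Φ_j. Latent labels z_i
assign pixels to components (panicle, leaves, dark background, …). All
parameters are learned per image by Gibbs sampling: each sweep draws

* **q** | z ~ Dirichlet(α + n) with n the component counts,
* Φ_j | μ_j, X_j ~ Wishart_p(S_j⁻¹, n_j) with S_j the scatter about μ_j,
* μ_j | Φ_j, X_j ~ N_p(τ_j*, (n_j Φ_j + Ω_j)⁻¹),
* z_i | … ~ categorical with Pr(z_i = j) ∝ q_j N_p(x_i; μ_j, Φ_j⁻¹),

and the posterior class probabilities Pr(z_i = j | X) are estimated by
averaging label indicators over the post-burn-in sweeps. The panicle
component is the one with the largest total channel mean
m_i = μ_i,r + μ_i,g + μ_i,b (panicles are the brightest canopy class); a
pixel is declared panicle when its panicle posterior reaches a threshold
p_TH (default 0.9990), which trades recall against precision and traces
the ROC curve. When segmenting with extra components (k > 3), clusters
whose means lie within ε_m = 0.1 of each other are merged (illumination
splits), and clusters with m_i ≥ ε_a = 0.9 are flagged as anomalies
(e.g. white field markers) and excluded before panicle identification.

The package ships a synthetic canopy-scene generator with exact pixel
labels, so the entire method is testable end to end without any field
imagery, plus a k-means++ baseline segmenter and a pixel-level evaluation
harness (recall / precision / F1 / ROC).

## Worked example

```python
import numpy as np
from paniclegmm import (GibbsGMMSegmenter, confusion, metrics,
                        default_scene_spec, generate_scene)

spec = default_scene_spec(200, 200, seed=42)
pixels, labels = generate_scene(spec)
truth = labels == 3  # class 3 of the default spec is "panicle"

model = GibbsGMMSegmenter(k=3, n_iter=150, burn_in=75,
                          p_th=0.9990, random_state=42).fit(pixels)
print("component total means:", np.round(model.component_total_means_, 4))
print("panicle component:", model.panicle_component_)
print("panicle pixels flagged:", int(model.panicle_mask_.sum()))

m = metrics(confusion(model.panicle_mask_, truth))
print(f"recall={m.recall:.4f} precision={m.precision:.4f} f1={m.f1:.4f}")
```

Output:

```
component total means: [0.7999 0.4299 0.1895]
panicle component: 1
panicle pixels flagged: 2553
recall=1.0000 precision=1.0000 f1=1.0000
```

The three fitted components order themselves by total channel mean —
panicle (0.80), leaf (0.43), background (0.19) — so component 1 is the
panicle class; 2 553 of the 40 000 pixels (6.4 %) exceed the posterior
threshold, and on this well-separated synthetic scene the mask matches
the ground truth exactly. On real imagery the classes overlap more and the
threshold genuinely trades precision for recall.

There is also a command-line interface:

```bash
paniclegmm simulate --image-out scene.png --mask-out truth.png
paniclegmm segment --input scene.png --output mask.png --truth truth.png \
    --posterior-map post.npy
paniclegmm roc --posterior-map post.npy --truth truth.png --out roc.tsv
```

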