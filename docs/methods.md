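# Methods

## Model

Each pixel of an image is a vector x_i ∈ [0, 1]^p of channel intensities
(p = 3 for RGB; 8-bit inputs are divided by 255). Pixels are modelled as
independent draws from a k-component multivariate Gaussian mixture:
latent labels z_i ∈ {1, …, k} follow a categorical distribution with
weights q, and x_i | z_i = j ~ N_p(μ_j, Φ_j⁻¹). Components are
parameterized by their precision matrix Φ_j rather than the covariance:
every density evaluation and every full-conditional draw then needs only
Cholesky factorizations, never an explicit matrix inverse.

Priors: q ~ Dirichlet(α) with α_j = 1 (flat); μ_j ~ N_p(τ_j, Ω_j⁻¹) with
τ_j = 0 and Ω_j = 10⁻³ I (weak — the data dominate after a few dozen
pixels); and the improper non-informative prior π(Φ_j) ∝ |Φ_j|^((p+1)/2),
under which the full conditional of Φ_j is Wishart_p(S_j⁻¹, n_j). That
improper prior is used as stated; its posterior is proper whenever the
component holds at least p linearly independent residuals.

Spatial dependence between neighbouring pixels is deliberately not
modelled: each pixel is classified from its color alone. Misclassified
stems/bright specks are the price; the gain is a model whose parameters
can be learned from a single unlabelled image.

## Sampler

One Gibbs sweep updates, in this fixed order: q | z; then for each
component j the pair Φ_j | μ_j, X_j followed by μ_j | Φ_j, X_j; then all
labels z | q, μ, Φ. Any fixed sweep order is a valid Gibbs scheme; this
one conditions each precision on the current mean and each mean on the
fresh precision, matching the stated full conditionals. All randomness
comes from a single `numpy.random.Generator` seeded once, and draws
consume the stream in the order above — two runs with the same seed,
configuration and input are bit-identical, which is part of the test
surface.

Label probabilities are computed in log space and normalized by
log-sum-exp. This matters: the operating threshold p_TH = 0.9990 lives in
the tail, and naive linear-space evaluation underflows for well-separated
components.

Defaults T = 150 sweeps with burn-in T0 = 75. The retention convention is
pinned exactly: iterations T0 … T inclusive are retained (the first
T0 − 1 = 74 samples are discarded, leaving T − T0 + 1 = 76), and
`ChainTrace.n_retained` exposes the count so tests can be exact. The
posterior probability estimate is the indicator average
Pr(z_i = j | X) ≈ (1 / n_retained) Σ 1{z_i = j} over retained sweeps.

**Label switching.** Mixture components are exchangeable, so the chain
may permute them. At every retained iteration the state is relabeled so
total channel means m_j = Σ_c μ_j,c are non-increasing in j before
indicators are accumulated; component 1 is therefore always the brightest
class. Relabeling per retained sweep (not once at the end) is required
for the indicator averages to be meaningful under label switching.

**Degenerate cases**, all pinned for reproducibility:

* Empty component (n_j = 0): the Wishart posterior is undefined, so the
  previous Φ_j is retained and μ_j is drawn from its prior (the n_j = 0
  limit of its full conditional).
* n_j < p or singular scatter: S_j is ridged by `ridge · I`
  (default 10⁻⁶) and, since a Wishart with fewer than p degrees of
  freedom is singular and unusable as a precision, the degrees of freedom
  are raised to max(n_j, p).
* Wishart draws use the Bartlett construction on a triangular factor of
  S_j⁻¹ obtained by triangular solve from the Cholesky factor of S_j.
* Argmax ties (MAP rule, panicle identification) break to the lowest
  index; the panicle-mask comparison is inclusive (posterior ≥ p_TH).

## Initialization

k-means++ (3 restarts, best within-cluster sum of squares, seeded)
partitions the pixels; initial weights are cluster frequencies n_j/n,
initial means the cluster means, initial precisions the inverses of the
within-cluster ML covariances (ridged when a cluster has < p + 1 members
or a condition number above 10¹²). Empty-cluster relocation is delegated
to scikit-learn's KMeans, which re-seeds an emptied centroid at distant
points. The same clustering serves as the classical baseline segmenter,
with the panicle cluster again chosen by total channel mean.

## Post-processing

With k > 3 components, illumination can split one physical class across
clusters, and bright anomalous objects get their own cluster. Two
repairs run on the post-burn-in summary (no re-sampling):

* **Merge**: clusters with ‖μ_i − μ_j‖ < ε_m (default 0.1) merge.
  The pairwise rule is closed transitively — connected components of the
  under-threshold graph — the unique order-independent closure. Merged
  means are weighted averages (weighted by posterior mass; pixel-count
  weighting would differ only where the chain is undecided) and merged
  posterior columns are summed, conserving each pixel's unit mass.
* **Anomaly detection**: merged clusters with total channel mean
  m_i ≥ ε_a (default 0.9) are flagged and excluded before the panicle
  component is chosen; with an anomaly present the panicle is then the
  second-brightest cluster. If every cluster is flagged there is no
  candidate panicle and the pipeline raises rather than guessing.

ε_a = 0.9 presumes the dim-canopy intensity regime (canopy classes sum
well below 0.9, white markers well above); for data in a brighter regime
the threshold must be raised or disabled (`eps_a=inf`).

## Synthetic scenes

`generate_scene` emulates the statistical structure the model assumes:
a small number of intensity classes whose class-conditional RGB values
are multivariate Gaussian. Elongated panicle ellipses, dark background
patches and (optionally) rectangular anomaly patches are painted over a
leaf canvas until each class reaches its target prevalence; pixel colors
are then drawn from each class's Gaussian and clipped to [0, 1] — the way
a saturating camera behaves, and a deliberately small model mismatch (the
default specs keep the clipped fraction below 1 %).

Default class means (leaf 0.10/0.25/0.08, background 0.06/0.08/0.05,
panicle 0.30/0.28/0.22, anomaly 0.85/0.85/0.82, isotropic sd 0.02) make
total channel means order panicle > leaf > background with the panicle
sum below ε_a and the anomaly sum above it; the default panicle
prevalence of 6 % sits inside the 3.7–8.5 % range typical of
heading-stage paddy canopies. The illumination-split variant adds a
second leaf class offset by 0.05 per channel (mean distance ≈ 0.087,
inside the merge radius).

What the scenes do **not** emulate: spatially correlated noise, smooth
illumination gradients, mixed boundary pixels, water reflections, and
class-conditional departures from Gaussianity. Passing tests on these
scenes therefore validate the inference machinery — samplers,
identifiability handling, thresholding, merging — not field performance;
on real imagery the classes overlap and precision/recall genuinely trade
off along the ROC curve. `iid_pixels` drops even the spatial painting
and draws labels i.i.d., which is the model's own generative process and
the reference input for parameter-recovery checks.

## Problem sizes and numerical checks

The validation suite runs at desk scale, chosen so each check has clear
statistical resolution: conjugate closed-form comparisons on a
single-component chain (n = 500, 251 retained sweeps, agreement within 3
Monte-Carlo standard errors); a frozen-parameter chain (20 pixels, 50 000
retained sweeps, binomial SEs ≈ 0.002); parameter recovery on 10 000
i.i.d. draws with class means ≥ 0.2 apart per channel (posterior means
within 0.05 of truth, MAP adjusted Rand index ≥ 0.95); and full-pipeline
segmentation of 200 × 200 scenes at T = 150 / T0 = 75. Larger images are
a linear-time extension (the per-sweep cost is O(n·k·p²)).

## Known limitations

* k is user-chosen; too large a k fragments classes and costs precision.
  The merge step mitigates moderate over-segmentation but does not select
  k automatically.
* The brightness-ordering rule assumes panicles are the brightest
  non-anomalous class; scenes violating that (e.g. overexposed leaves)
  misidentify the panicle component.
* Uniform within-image illumination is assumed; strong gradients break
  the single-Gaussian-per-class assumption.
* The improper precision prior requires components to keep at least p
  independent residuals; the ridge path keeps the sampler running on
  degenerate components but is a regularization, not a posterior.
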