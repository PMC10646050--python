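# Methods

## Problem setting

During brain-tumour resection the surgeon must judge, in the open surgical
field, where diffuse tumour tissue ends and functional tissue begins.
`hsibrain` implements a label-free optical approach: a visible/near-infrared
pushbroom hyperspectral camera captures a cube of 826 spectral channels over
400–1000 nm for every exposed-cortex scene, and a processing chain classifies
each pixel as normal tissue (NT), tumour tissue (TT), blood vessel (BV) or
background (BG), then renders a three-maximum-density (TMD) map in which the
red/green/blue intensity of each spatial region encodes its TT/NT/BV density.

## Pre-processing chain

The chain is fixed and stage-stamped; each operation refuses out-of-order
input.

1. **Radiometric calibration.** `CI = (RI − DI) / (WI − DI)` per element,
   with `WI` a white-tile reference captured under the surgical illumination
   and `DI` a closed-shutter dark frame. Elements where `WI ≤ DI` are
   undefined; they are zeroed and tolerated up to a configurable fraction
   (default 5%). Negative reflectance from sensor noise is clipped to 0.
2. **Extreme-band removal.** The sensor is noisy at its spectral extremes;
   only channels with centre wavelength in **[440.5, 909.1] nm** are kept.
   On the uniform 826-point grid over [400, 1000] nm (spacing 600/825 ≈
   0.727 nm) this retains exactly **645** channels. We crop by wavelength
   window rather than by channel index: the two conventions disagree by one
   channel, and the window is the contract the rest of the chain depends on.
3. **Spectral smoothing.** Centred moving average, window 5 samples, with
   truncated windows at the spectral edges so band count is preserved.
4. **Decimation.** Uniform stride-5 subsampling of the 645 channels starting
   at index 0, truncated to the first **128** selections. Mean sampling
   interval on this grid is 3.64 nm.
5. **Per-pixel min–max normalization** to [0, 1]. This removes per-pixel
   illumination scale (any positive affine transform of a spectrum maps to
   the same output), which matters because intra-operative illumination is
   uneven. Constant spectra cannot be scaled; they map to zero and are
   flagged degenerate rather than failing.

For spectral characterization, reflectance converts to absorbance as
`A(λ) = −log10 R(λ)` (base-10, the standard absorbance convention), with
non-positive reflectance clipped to a small floor.

## Labelling

Ground truth is sparse: only pixels an operator marks with high confidence
are labelled. The semi-automatic tool is built on the spectral angle mapper,
`SAM(a, b) = arccos(⟨a,b⟩ / (‖a‖‖b‖))`, which is scale-invariant, so a
threshold on the angle to a seed spectrum selects pixels of similar spectral
*shape* regardless of brightness. Selection is purely spectral — spatial
connectivity is deliberately not enforced — and returns a delta map for
review before merging. Label maps serialize as paletted PNGs (red = TT,
green = NT, blue = BV, black = BG, white = unlabelled).

## Training-set reduction

Labelled pixels are abundant, redundant and imbalanced. Per class, K-means
(k-means++, K = 100 centroids) summarizes the class manifold; each centroid
then claims the *n* labelled pixels of its class with the smallest spectral
angle to it (n ∈ {10, 20, 40}; default 10), yielding exactly 100·n pixels
per class. Assignment is without replacement, processed globally in order of
increasing angle, so a pixel wanted by two centroids goes where it ranks
best and the exact count is preserved. Ties break by pixel index. The
reduced set is a *selection* of real pixels, never synthetic averages.

## Validation design

Splits are drawn at **patient** level — 60% train / 20% validation / 20%
test, sizes rounded half-up with every split clamped to ≥ 1 patient — so no
patient's pixels can appear on both sides of a model (inter-patient
validation). Five independently seeded folds are drawn by default.
Hyperparameters are chosen per fold by coarse grid search maximizing
validation macro F1 with BG excluded; grids are log-decade ladders for SVM
cost/width (10⁻³…10³), 50–500 trees for the forest, odd 1–39 neighbour
counts, and hidden sizes {16, 32, 64, 128, 256}. Ties resolve to the
lowest-complexity point, scanned in increasing order.

## Classifiers

Six model kinds emit 4-class posteriors per pixel: linear and RBF SVMs
(one-vs-one, pairwise-coupled sigmoid calibration), random forest (tree-vote
fractions), Euclidean and cosine k-NN (neighbour-vote fractions), and a
two-hidden-layer dense network (ReLU, SGD with learning rate 0.1, mini-batch
128, a fixed 300 epochs with no early stopping). For the network, feature
standardization is applied in front of the net; it plays the normalisation
role that batch-norm layers play in larger frameworks and is what keeps the
aggressive 0.1 learning rate stable (without it the loss diverges). All
posteriors are clipped to ≥ 0 and renormalized so every pixel lies on the
probability simplex; class maps are posterior argmaxes.

## Spatial–spectral fusion

Spectral classification is per-pixel and therefore speckled. Spatial context
is injected in three steps:

* **PCA guide image** — the first principal component of the cube's own
  pixels, min-max rescaled to [0, 1]; a one-band structural summary.
* **Guided KNN filtering** — each pixel's posterior is replaced by the mean
  over its K = 40 nearest neighbours in the feature space
  `f(j) = (row_j/w, col_j/w, λ·g_j)` with λ = 1, guide value `g`, and
  candidates restricted to ± w = 8 image rows (Euclidean distance). Scaling
  the spatial coordinates by the window height puts one window-height of
  distance on par with the full guide range, so λ genuinely trades intensity
  against space. The published description fixes λ, K, the window and the
  metric but not the feature formula; this construction is our convention
  and is logged as such. Averaging is convex, so outputs stay on the simplex
  and inside the convex hull of the inputs.
* **Hierarchical k-means (HKM)** — bisecting k-means: repeatedly 2-means
  split the cluster with the largest within-cluster sum of squares until
  K_seg = 24 clusters remain (k-means++ init, seeded).
* **Majority voting** — each cluster takes the modal class of the filtered
  class map; ties break to the lowest class code (NT < TT < BV < BG).
* **TMD rendering** — each cluster is painted RGB = (fraction TT, fraction
  NT, fraction BV) computed over *all* its pixels, BG included in the
  denominator, so BG-heavy clusters render dark and R+G+B = 1 exactly when
  the cluster is BG-free.

## Evaluation

Per class, one-vs-rest confusion counts over labelled pixels only give
F1 = 2TP/(2TP+FP+FN), sensitivity TP/(TP+FN) and specificity TN/(TN+FP);
overall accuracy is the fraction of labelled pixels classified correctly.
**Macro F1 averages F1 over NT, TT and BV only** — BG is excluded so that
an easy, abundant background cannot mask poor tumour delineation. Spectral
populations are compared channel-by-channel with a two-sided Wilcoxon
rank-sum (Mann–Whitney) test at the 5% level: group sizes are unequal, so
the unpaired form is the only applicable one; small untied samples
(combined n ≤ 16) use the exact null distribution, larger ones the
tie-corrected normal approximation with continuity correction.

## Phantom generator

Clinical HS databases are access-restricted, so the package ships a
generator whose defaults define the test conditions used throughout.

Forward model per pixel: absorbance is a chromophore mixture
`A = h·(c_HbO2·ε_HbO2 + c_dHb·ε_dHb) + baseline`, reflectance `R = 10^−A`,
raw counts `R·(WI−DI)·falloff + DI + N(0, σ)`. The extinction shapes are
**synthetic** Gaussian-peak approximations (oxyhaemoglobin peaks near
542/576 nm, deoxyhaemoglobin near 555 and 760 nm); only relative shape
matters to a pipeline that normalizes per pixel. Class defaults encode the
qualitative orderings seen in vivo: NT is oxygenated (no 760 nm dip), TT is
markedly deoxygenated (visible 760 nm dip, absorbance above NT), BV has the
strongest absorbance, BG is a chromophore-free dark ramp.

Realism features, chosen once as generator design: a smooth multiplicative
heterogeneity field on the chromophore term (sd 15%, correlation length 6 px
— tissue is not optically uniform), Gaussian partial-volume blur of the
class abundances at boundaries (σ = 1.2 px — boundary pixels are genuine
mixtures, the ambiguity the spatial stage exists to resolve), radial
illumination falloff absorbed into the white reference (so calibration
divides it out, as with a real tile captured under the same illumination),
and i.i.d. Gaussian sensor noise, default σ = 0.02 of the white–dark span.
The default scene is 160×160 px: an elliptical tumour, two Bézier vessel
curves (8 px wide ≈ 1 mm at the camera's 128.7 µm pixel pitch), and a
background frame. Ground truth follows the clinical high-confidence
convention: only pixels whose dominant class abundance is ≥ 0.9 after the
partial-volume blur are labelled, so ambiguous boundary mixtures stay
unlabelled exactly as an operator would leave them; the dense layout
partition remains available separately for segmentation experiments. With
noise, heterogeneity and blur all zero, calibration inverts the forward
model exactly — a frozen identity test.

What the phantom does **not** model: specular glare, motion, depth-resolved
scattering, out-of-focus deep tumour margins, instrument clutter, or
inter-patient pathology diversity beyond small random scalings of the class
optics. Passing phantom tests therefore demonstrates correctness of the
machinery and recoverability under controlled conditions, not clinical
performance.

## Experiment sizes

Desk-scale experiments use 160×160-pixel scenes, 8 synthetic patients with
one capture each, a single fold per seed and three seeds for recovery
claims; the k-NN classifier with N = 5 is the default end-to-end model.
These sizes were chosen so a full recovery experiment completes on a single
CPU while leaving every contract (645/128 bands, 100·n reduction, 24
clusters, 60/20/20 splits) at its full published value.

## Numerical choices and degenerate inputs

* Smoothing edge policy: truncated windows (length-preserving).
* Calibration floor: reflectance clipped to ≥ 0 before log/normalize stages.
* Constant spectra: flagged degenerate, mapped to zeros, never fatal.
* K-means: k-means++ with seeded, small restart counts (3 for the reducer);
  bisecting k-means uses the library default single initialisation per
  split, seeded.
* SAM of a zero pixel against any reference is treated as maximally
  dissimilar (angle π) in vectorized form, and rejected for explicit
  scalar queries.
* All-zero posterior rows (possible for degenerate pixels) renormalize to
  the uniform distribution rather than NaN.

## Known limitations

* Clinical-scale in-vivo HS brain databases are access-restricted
  (available on request from their custodians); every result this package
  computes is phantom-derived, and nothing here reproduces or estimates
  clinical performance.
* The EBEAE/NEBEAE unmixing classifiers are registered as model-kind names
  with their published per-class settings recorded in configuration, but no
  estimator is implemented for them.
* The guided-filter feature construction is a documented convention (see
  above), not a published formula.
* The network classifier substitutes input standardization for batch
  normalization; with standardized inputs and the fixed 300-epoch budget the
  substitution is stable, but it is not layer-wise normalization.
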