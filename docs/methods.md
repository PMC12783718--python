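# Methods

`cryptomorph` implements an explainable computer-vision workflow for asking
whether genetically defined groups ("clades") of a species differ in
morphology even when no difference has been described by eye. The workflow
is: classify standardized specimen images by clade with a small CNN under a
repeated resampling protocol; control the experiment with randomized
mixed-group labels; locate the image regions driving classification with
SmoothGrad saliency; and quantify the highlighted structure with mask-based
shape descriptors and Karcher-mean outline comparison. Because the package
must be testable without a collection of photographed specimens, it ships a
synthetic shell-image generator whose clade effects are planted with known
magnitudes, so every downstream stage can be checked against ground truth.

## The synthetic generator

Each specimen is a filled shell outline rendered on a black background
(grayscale, default 256×256 — chosen so the ~28-px keyhole is wide enough
for faithful sub-pixel contour morphometry; at half this resolution the
binary quantization of the ~3-px waist half-width attenuates the planted
quartile/central ratio by ~0.1) with a ground-truth shell mask, an optional
keyhole-aperture mask, and metadata (species preset, clade, location,
orientation, caliper size in mm).

**Keyhole geometry.** The keyhole boundary comes from the half-width profile

    halfwidth(h) = (W/2) · sqrt(1 − (2h/H − 1)²) · (1 − p·exp(−(h − H/2)²/(2σ²)))

for heights `h ∈ [0, H]`, mirrored about the vertical axis: an ellipse of
width `W` and height `H = 2W` carrying a Gaussian waist ("pinch") of
amplitude `p ∈ [0, 1)` and width `σ = 0.15·H`. The Gaussian kernel localizes
the indentation at mid-height, so the widths at 25% and 75% of the height
exceed the central width — the "more indented, less circular" Northern form.
Two clade contrasts are planted:

- the Northern population-mean width is `(1 − keyhole_narrowing)` times the
  Southern (default 0.12, i.e. 12% narrower);
- the Northern pinch amplitude defaults to `p = 0.4623`, the closed-form
  solution of mean-quartile-width / central-width = 1.425 at `σ = 0.15H`
  (`solve_pinch_for_ratio` inverts the linear relation
  `R = (√3/2)(1 − qp)/(1 − p)` with `q = exp(−1/(32σ²))`).

**Shell geometry.** The shell boundary is `r(θ) = R(1 + Σ a_k cos(kθ + φ_k))`
with low-order random harmonics plus narrow Gaussian ridge bumps in `θ`
(count 9, clade-specific amplitude); larger bumps lower solidity and extent.

**Presets.** `keyhole_like` carries the full keyhole contrasts;
`weak_signal_like` scales every clade contrast to 25% (a weakly diverged
species); `ridge_like` drops the keyhole and contrasts ridge amplitude;
`band_like` contrasts only concentric band intensity (a non-geometric cue).

**Within-clade variability.** Per specimen, `W` and `H` receive
multiplicative lognormal noise (sd 0.10), the pinch receives additive
Gaussian jitter (sd 0.05, clipped to [0, 0.95]), and outlines receive
low-order Fourier boundary jitter (per-harmonic sd 0.012). These sds are
free design parameters chosen to give visible within-clade spread without
swamping the planted contrasts; no empirical estimate of real within-clade
keyhole variance was available to calibrate them.

**Sizes.** Caliper sizes are drawn from one normal distribution shared by
both clades (mean 18.3 mm, the keyhole-limpet average; sd 2.5 mm), so clade
size distributions overlap fully and rank tests on size are non-significant
— size cannot be the cue the classifier uses. Rendering couples specimen
size mildly to on-frame scale (clipped to ±30%).

**What the generator does not emulate.** Photographic texture, erosion,
lighting gradients, 3-D relief, color; location-specific morphology (all
within-clade locations are statistically identical). Passing tests
therefore demonstrate that the pipeline recovers planted geometric signals
through rendering and mask extraction — not that any real species differs.

## Resampling protocol

Per iteration (seed = base seed + iteration index): locations contributing
more than `location_cap` specimens (default 100) are randomly thinned, the
overflow joining the test pool, so an over-sampled site cannot dominate
training. Per class, 120 training and 30 validation specimens are drawn
(desk scale: 60/15); the remainder plus overflow form the Full-test pool,
from which a class-balanced Even-test (20 per class) is drawn; the four id
lists are disjoint and conserve the input. Training and validation batches
are augmented on the fly (rotation ±30°, horizontal/vertical flips at
probability 0.5, scale 0.9–1.1 — unremarkable defaults; the protocol fixes
only that test images are never augmented). The mixed-group control
relabels the pool into two synthetic classes containing exactly equal
numbers of true-Northern and true-Southern specimens, re-drawn each
iteration from the iteration seed; true labels remain on the records as the
audit channel.

## Classifier

A deliberately small, fully deterministic NumPy CNN: 3×3 same-padded conv
blocks with ReLU and 2×2 max-pooling (default channels 16/32/64), a ReLU
dense layer (64), a 2-way linear head, softmax cross-entropy and Adam
(lr 1e-3), early stopping on validation loss with best-weight restore.
Writing the network directly in NumPy keeps training bit-reproducible from
a seed and gives exact input gradients (verified against finite differences
in the test suite), which SmoothGrad needs. A backbone hook accepts any
object exposing `predict_scores` and `input_gradient`.

Desk-scale defaults used by the acceptance runs: 48-px inputs (the input
must still resolve the keyhole, ~5 px wide after downsampling; coarser
inputs blur away exactly the feature under study), channels 8/16/32, 15
epochs, patience 4, 20
iterations; classifier inputs are downsampled from the rendered images, so
classification cost is decoupled from the rendering resolution the
morphometry needs. F1 is reported as macro-F1 — the unweighted mean over classes
of 2PR/(P+R), with the convention that a class with no predicted positives
has precision 0 and F1 0; on the balanced Even-test macro and per-class F1
nearly coincide. Per-class values are always retained.

## Saliency

SmoothGrad: average the absolute input gradient of the target-class score
over 25 copies of the image perturbed with Gaussian noise of sd 0.15 × the
intensity range (the method's customary operating range), then normalize to
unit maximum. Attribution defaults to the predicted class. Attention is
quantified per region as `region_fraction` (saliency mass inside the
ground-truth mask over total mass) and `enrichment` (`region_fraction`
divided by the region's area fraction); enrichment > 1 on clade-trained
models but not on mixed-group controls is the quantitative counterpart of
"the heatmaps highlight the keyhole".

## Shape descriptors

Masks are converted to sub-pixel contours by marching squares at level 0.5;
components of ≥ 100 px are first smoothed with a Gaussian of σ = 0.8 px,
because the 0.5-level contour of a hard binary mask follows pixel
staircases and overestimates perimeters by ~5%, which would wreck the
circularity calibration (a rasterized disc of radius 30 px then measures
its circumference to 0.7%). Components under 9 px are rejected; masks with
more than one large component raise a segmentation error listing component
sizes.

Outlines are normalized to centroid origin, best-fit-ellipse major axis
vertical, major-axis length exactly 1.0 (uniform scaling, so aspect is
preserved and descriptors measure shape, not size). All quantities are
exact polygon integrals (shoelace area, segment-sum perimeter, closed-form
second central moments); the best-fit ellipse is the one sharing the
region's second moments, giving axis lengths `4√λ`. The five descriptors:
circularity `4πA/P²`, eccentricity `√(a²−b²)/a`, solidity (area over convex
hull area, via an exact hull of the contour vertices), extent (area over
the object-aligned bounding box — taken after normalization rotation, since
an image-aligned box would make extent depend on arbitrary orientation),
and minor-axis length `b/a`.

## Karcher mean and landmarks

Outlines are resampled to k = 200 points equally spaced by arc length,
starting from the topmost point. The mean shape iterates two exact steps:
optimally align every outline to the current mean (translation, rotation
and cyclic start-index roll computed jointly via the complex
cross-correlation FFT; reflections are excluded; scale is untouched since
all inputs are normalized), then replace the mean by the point-wise
average. This is plain two-block coordinate descent on the summed squared
residual, so the objective is non-increasing by construction, which the
implementation asserts. The mean is renormalized (major axis vertical,
length 1.0) and resampled once, at convergence (mean RMS displacement
< 1e-6, max 100 iterations): performing either operation inside the loop
injects a small scale/parametrization perturbation each pass that breaks
the monotonicity guarantee without improving the estimate. Fixed points
from different initializations agree only up to the discrete roll
correspondence and the stopping tolerance (empirically ~1e-2 RMS on noisy
data), which the tests treat as the method's resolution.

Landmarks: the outline's height is its vertical extent; horizontal lines at
25/50/75% of height (from the bottom — the generated shapes are symmetric
enough that the direction is immaterial) intersect the margin, and the
extreme left/right crossings at each level are the six landmarks (extra
crossings at non-convex heights resolve to the extremes, logged). Widths
are the within-level landmark distances. The clade contrast reports
`100·(minor_S − minor_N)/minor_S` (Southern, the wider form, as baseline)
and each clade's `mean(width_25, width_75)/width_50`.

**A geometric caveat on the minor-axis contrast.** The two planted keyhole
contrasts interact: a central pinch deep enough to drive the
quartile/central ratio to 1.425 removes interior area near mid-height and
therefore shrinks the moment-based minor axis far beyond the planted 12%
width narrowing (closed-form/numeric evaluation of the profile gives ~38%,
which is what the full pipeline measures). With this generator and this
minor-axis definition the two numbers cannot be recovered simultaneously;
the pipeline's recovery test documents the ratio recovery and this
measured minor-axis behaviour. Real keyholes whose quartile widths exceed
the central width by bulging outward (rather than pinching inward) would
not show this coupling.

## Statistics

Mann-Whitney U (exact enumeration null for combined n ≤ 16 without ties,
else normal approximation with tie and continuity corrections — the exact
path is verified against full enumeration in the tests), Kruskal-Wallis
with tie correction, and a seeded percentile bootstrap for medians. The
per-metric clade comparison reports unadjusted p-values (the planted-effect
checks key on these) alongside a Bonferroni column. All alternatives are
two-sided. Box plots use median/IQR with 1.5·IQR whiskers.

## Problem sizes

The shipped experiment sizes are: 200 specimens per clade, 20 resampling
iterations per configuration (5 for the weak-signal ranking), 48-px model
inputs, k = 200 mean-shape points, 25 SmoothGrad samples. These are the
package's reference desk-scale conditions; the full-scale protocol values
(120/30/20 per class, 100 iterations, 100-specimen location cap) remain the
configuration defaults.

## Known limitations

- The generator's shapes are smooth parametric families; real shell masks
  carry segmentation noise, erosion and damage the pipeline never sees here.
- The classifier is intentionally small and CPU-bound; absolute F1 values
  on real photograph collections (with transfer-learned backbones) are out
  of scope — orderings and control behaviour are the reproducible content.
- Mixed-group saliency enrichment hovers near 1 but inherits variance from
  whichever arbitrary features a chance-level model latches onto; it is a
  distributional statement, not a per-model guarantee.
- One orientation ("dorsal") is rendered; per-orientation experiments would
  simply repeat the pipeline per view.
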