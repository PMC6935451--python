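# Methods

This note records the models, conventions and numerical choices behind
thermoseg, in the order the pipeline applies them, together with what the
synthetic phantoms do and do not establish about real thermograms.

## Preprocessing and margin extraction

The RGB thermogram is converted to gray with Rec. 601 luminance weights
(0.2989, 0.5870, 0.1140), normalized to sum exactly to one so a white
pixel maps to 1.0. Denoising uses a 3×3 Gaussian; since only the kernel
size is fixed by the operating point, the sigma is taken as kernel/6
rounded to the nearest half pixel (0.5 px for the 3×3 kernel), i.e. the
kernel holds the ±3σ support. Convolution uses reflect padding to avoid
darkening at image borders.

Binarization keeps pixels with gray intensity strictly above 0.25. Margin
extraction accepts either one dominant foreground component spanning both
image halves (split at the vertical midline) or two components, one per
half; smaller components under 20 px are treated as noise. Boundaries are
traced with Moore-neighbour following, yielding closed 8-connected pixel
chains. An edge-detection backend (Canny) would be interchangeable here;
direct tracing of the thresholded component is used because the scene is
already binary at this stage.

**Orientation convention.** Curvature sign depends on traversal direction,
and the side-specific peak convention (curvature maxima delimit the right
breast, minima the left) can only hold for mirror-symmetric margins if the
two curves are stored with mirrored orientations. thermoseg therefore
stores the right margin with positive signed (shoelace) area in (x, y)
image coordinates and the left margin with negative signed area. With the
curvature definition k = (ẋÿ − ẍẏ)/(ẋ²+ẏ²)^{3/2}, a convex arc then has
k > 0 on the right margin and k < 0 on the left margin.

## Curvature and initialization

Coordinates are smoothed circularly with a 1-D Gaussian (default σ = 3
points) and differentiated with circular central differences. (Analytic
derivative-of-Gaussian kernels were rejected: the sampled second-derivative
kernel has a large relative error at the very low spatial frequencies of
smooth anatomical boundaries.) The parametrization-invariant curvature
formula tolerates the non-uniform spacing of 8-connected chains once the
coordinates are smoothed. Verified accuracy: < 0.1% error on a 720-sample
circle of radius 50, < 0.01% at the vertex of a 2000-sample 100×50
ellipse.

Peaks use a prominence floor of 0.005 px⁻¹ (configurable); with no peak
above the floor, the two points of extreme correctly-signed curvature act
as delimiters. The margin points between the outermost peaks (or the
complementary arc when that span covers less than 25% of the curve) are
fitted with a direct least-squares ellipse (Halir–Flusser, via
scikit-image's `EllipseModel`); degenerate conics raise an initialization
error rather than silently falling back to a circle. The fitted ellipse,
contracted radially by 0.95 and sampled at 200 vertices, seeds the snake
just inside the breast boundary.

## Edge map, GVF and snake evolution

The external energy combines three terms computed from the denoised gray
image at Gaussian scale σ = 3 px (configurable): the smoothed intensity
(line term; warm tissue is bright, so brightness attracts), the squared
gradient magnitude of the smoothed image (edge term), and the level-line
curvature (termination term), with weights w_l = 0.01, w_e = 0.40,
w_t = 0.01. **Each term is rescaled to unit peak magnitude before
weighting.** This matters: for smoothed anatomical edges the raw squared
gradient is orders of magnitude smaller than the raw intensity, and
combining unscaled terms would let the nominally small line weight
dominate — the field would then drag the contour toward the bright
interior rather than the boundary. With unit-peak terms the printed
weights express the intended dominance of the edge term. The combined map
is shifted to be non-negative; the pipeline additionally rescales it to
[0, 1] so the external force scale κ is contrast-independent.

The GVF field is computed by explicit diffusion iterations
(u ← u + dt·(μ∇²u − |∇f|²(u − f_x)), likewise v), initialized at ∇f, with
μ = 0.2 and 200 iterations by default and a hard stability check
4·μ·dt ≤ 1. The iteration monotonically decreases the GVF energy
functional and converges to the solution of the Euler–Lagrange system
(verified against a direct sparse solve in the tests).

For snake evolution the pipeline uses the **direction-normalized** field
(u, v)/|(u, v)| as the external force — the classic practice for GVF
snakes: it makes the pull toward the boundary depth-independent inside the
capture range, so initializations from 0.8× to 1.1× of the true boundary
all converge (phantom checks reach ZSI ≈ 0.997 across that range, where
the raw-magnitude force stalls below 0.9× because the diffused magnitude
falls under the internal tension).

The snake update is the standard semi-implicit scheme: the cyclic
pentadiagonal internal-force system (elasticity α = 0.20, rigidity
β = 0.20, step γ = 1.00) is solved against κ·(u, v) sampled at the
vertices by bilinear interpolation (κ = 0.1). The run caps at 5000
iterations with early stop when the mean vertex displacement drops below
0.01 px. Every 50 iterations the polygon is resampled to uniform spacing
of about 1 px (vertex count clipped to [16, 2000]); the internal weights
are calibrated for unit spacing, and coarser spacing makes tension
quadratically stronger, which visibly shrinks large contours. A contour
whose area falls below 5 px² raises a collapse error. Conversion of the
converged polygon to a mask uses even-odd scanline fill with pixels whose
centers lie exactly on the boundary included; self-intersecting polygons
are filled with a warning.

## Features

Area is the foreground pixel count. The perimeter treats the region as a
union of unit pixel squares: its outline is extracted by marching squares
on a 4× refined grid and simplified by Douglas–Peucker at 1 px tolerance.
This estimator was chosen because it simultaneously reproduces 2(w+h) for
a w×h rectangle (within ~1%) and approaches the smooth circumference for
digitized circles as the radius grows (roundness 0.94 → 0.99 from r = 10
to r = 80), where raw chain-code length and Crofton-style estimators each
satisfy only one of the two.

Compactness follows the tabulated form C = A/P² (the A/P variant is
available behind a flag but is not part of the 155). The median is the
ordinary sample median of in-mask values — the grouped-data median formula
degenerates to it on ungrouped pixel data. Entropy uses the normalized
256-bin histogram over [0, 1], base 2 (bits), with 0·log 0 = 0. GLCMs
quantize each channel uniformly to 8 levels over [0, 1] at offset (1, 0),
symmetrized and normalized; correlation of a degenerate (constant) GLCM is
defined as 0. BD uses √|V_r·V_l| because base features such as GLCM
correlation can be negative, where the bare product form would be
undefined. ED and D coincide for scalar pairs; both are emitted to honour
the documented 93-value relation block, ordered per base pair as
(ED, BD, D).

## Classification

The tabular learners are scikit-learn's random forest (200 trees), MLP
(one hidden layer of 32 units, standardized inputs — the raw features mix
scales from ~10³ px² areas to ~10⁻² homogeneities) and Gaussian naive
Bayes. The CNN is a compact seeded NumPy implementation:
3×3-conv/ReLU/2×2-max-pool blocks (8 and 16 filters), a global max+mean
pooling head, one dense layer of 32 units and a softmax, trained
full-gradient with Adam (100 epochs, lr 3·10⁻³, batch 10). The global
pooling head replaces flattening because with tens of training images a
flattened head overfits positional jitter, while channel-wise pooling
keys on the localized activation peak a hot spot produces regardless of
its position. The default input side is 277 px to match the published
segmented-image input; experiments at reduced scale configure a smaller
side (32 px in the tests), which preserves the colour-asymmetry signal.

The positive class is *normal* (P = number of normal cases). All
indicators derive from one confusion matrix; zero-denominator indicators
are reported as NaN, never as 0. AUC is the Mann–Whitney rank statistic
with midranks for ties (scikit-learn's `roc_auc_score`). 2-fold splits are
stratified and seeded. ZSI is Dice overlap by construction.

## Synthetic phantoms

A phantom is a scalar temperature field on a 192×256 grid: cold surround
0.02, torso ellipse at 0.10, two breast ellipses (semi-axes ≈ 32×42 px,
one per image half) elevated by +0.30, optional Gaussian hot spot
(σ = 5–8 px, +0.30) inside one breast for abnormal cases, Gaussian edge
softening (σ = 1 px), additive Gaussian noise (sd 0.01), clipped to
[0, 1], then mapped through a fixed piecewise-linear blue→green→red
palette that is strictly monotone in hue position and invertible to within
quantization. The temperature levels are chosen so that, after gray
conversion, the torso stays below the 0.25 binarization threshold while
the breasts rise well above it — the threshold then isolates exactly the
two breast regions, as it isolates the warmest regions in a real
thermogram. Ground-truth masks are rasterized from the exact (unsmoothed)
ellipses. All randomness flows from one explicit seed; dataset generation
jitters centers (±6 px), axes (×0.9–1.1), rotation (±0.15 rad) and
elevations (±0.05) per sample.

**What passing phantom tests shows — and does not.** The phantoms exercise
the full geometric and photometric logic: margin tracing, curvature
delimitation, ellipse recovery, snake convergence, colour-asymmetry
features, classifier separation. They do not emulate physiological
vascular patterns, breast ptosis or contact regions, camera noise spectra,
emissivity artefacts, or the inter-patient variability of real cohorts;
classification accuracy of 1.0 on phantoms is a statement about the
pipeline's correctness on its model assumptions, not a clinical
performance claim. The phantom's abnormality cue (a localized Gaussian
temperature bump) is a minimal stand-in for a tumour signature.

## Problem sizes

The default test and evaluation sizes are 192×256 phantoms, 200-vertex
snakes, 20-phantom segmentation suites and 40-phantom classification
datasets with 32 px CNN inputs — sizes at which the full suite runs in
well under a minute on one CPU while every stage still operates in its
intended regime.

## Known limitations

* Frontal, two-breast scenes only; no lateral or rotational views.
* The threshold 0.25 presumes the pseudo-colour → gray mapping places warm
  tissue above it; radiometrically calibrated or differently-paletted
  inputs need a different threshold.
* The snake has no balloon force: an initialization far outside the
  capture range of the (normalized) GVF field will not converge; in the
  pipeline this is mitigated by the curvature-based ellipse fit, which on
  phantoms lands within a few percent of the true boundary.
* ED ≡ D for scalar pairs; the relation block is partially redundant by
  construction.
* The CNN is a deliberately small, seeded network for reduced-scale
  experiments; no claim is made of reproducing any particular trained
  architecture.
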