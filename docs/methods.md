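# Methods

This note documents the models, numerical choices and known limitations of
`lvseg`. It is written for users who need to judge what the package's tests
do and do not demonstrate about real cine-MR data.

## Segmentation model

### Local binary fitting (LBF) level set

The blood pool is localized by a two-phase region-based active contour whose
fitted intensities are *local*: at every point x, inside/outside intensities
f₁(x), f₂(x) are Gaussian-weighted averages (window σ) of the image over the
current inside/outside partition,

    f₁ = K_σ∗(H_ε(φ)·I) / K_σ∗H_ε(φ),
    f₂ = K_σ∗((1−H_ε(φ))·I) / K_σ∗(1−H_ε(φ)),

with the smoothed Heaviside H_ε(z) = ½(1 + (2/π)·arctan(z/ε)). Locality makes
the model robust to the smooth intensity inhomogeneity (bias field) typical of
cardiac MR, which defeats global two-phase models. The gradient-descent update
combines

* the data force −δ_ε(φ)(λ₁e₁ − λ₂e₂), with
  e_i(x) = ∫K_σ(y−x)|I(x) − f_i(y)|² dy expanded into three convolutions,
* an arc-length (curvature) term ν·δ_ε(φ)·κ, and
* a distance-regularization term μ·(Δφ − κ) that maintains a usable profile
  of φ without periodic redistancing.

**Parameters** (all exposed in the flat YAML config):

| parameter | default | units | role |
|---|---|---|---|
| λ₁, λ₂ | 1.0 | – | inside/outside data weights |
| σ | 3.0 | px | locality of the intensity fits |
| ν | 0.01·(intensity range)² | – | boundary smoothness |
| μ | 1.0 | – | φ regularity |
| timestep | 0.1 | – | explicit Euler step |
| ε | 1.0 | px | Heaviside/Dirac width |
| max_iter / tol | 300 / 10⁻³ | – / mean px | stopping rule |

φ is initialized as a binary step (±2) on the seed mask; the μ term restores
regularity, so no signed-distance reinitialization is needed.

**Numerical choices.** The Gaussian kernel is truncated at a half-width of
2σ+1 px and applied separably with replicate boundaries. Two choices matter
for robustness and are deliberate:

* The curvature κ = div(∇φ/‖∇φ‖) is computed with ‖∇φ‖ floored at 0.5. In
  flat regions of φ the unfloored normal field has arbitrary noise directions
  and its divergence is O(1) garbage; through μ·(Δφ − κ) that random forcing
  slowly flips the far field into speckle. With the floor, κ → ≈Δφ in flat
  regions, so the regularizer vanishes there and acts only near the interface,
  where ‖∇φ‖ ≈ 1 and the floor is inactive.
* ν defaults to 0.01·(range)² rather than a smaller weight. At the package's
  reference study condition (contrast-to-noise 10 with a ±10 % bias field) a
  weaker arc-length penalty lets isolated bright noise pixels seed persistent
  φ > 0 islands and lets the interface track noise; 0.01 suppresses both while
  a clean two-value disk is still recovered exactly (Dice 1.0).

The raw {φ > 0} region may legitimately contain other locally bright tissue
(right ventricle, fat). The pipeline therefore keeps the connected component
with maximal overlap against the contour mask — a centered binary circle on
the mid slice, the previous slice's endocardial region elsewhere — before any
further processing.

### Overlap-guided threshold refinement

The ROI is binarized at 24 thresholds evenly spaced between its 5th and 95th
intensity percentiles. For each threshold the 8-connected component with
maximal pixel-count overlap against the LBF pool is scored; the maximal
overlap wins. On the frequent overlap plateau the tie breaks toward the
candidate nearest the ROI's Otsu threshold (Otsu alone is biased when class
variances differ; the overlap criterion removes that bias and Otsu only
arbitrates exact ties). Holes are filled *after* component selection, so
papillary muscles and trabeculations end up inside the cavity, matching the
convention of the public challenge evaluation. A guard fails the slice when
the selected "pool" covers more than 60 % of the ROI — that configuration is
anatomically impossible and indicates a degenerate threshold (e.g. a
structure-free image).

### Endocardium and the LVOT branch

Marching mid→base, a slice is flagged as the LVOT-containing basal slice when
the moment-equivalent major axis of the blood pool's convex hull exceeds the
previous slice's by a factor > 1.2 (strict). The hull rather than the raw
pool is measured — the outflow leak is exactly what the hull exaggerates, and
the raw pool's axis is noisy at the pixel level. Marching mid→apex the test
is disabled (there is no outflow tract apically).

Without LVOT, the endocardial contour is the convex hull of the pool's
boundary pixels (convexity bridges papillary notches). With LVOT, the
binarized ROI is masked by the previous pool dilated with a disk of 3 px, the
masked boundary is expressed in polar form about the previous pool's center,
a Kåsa algebraic least-squares circle is fitted, points with polar radius
more than 3 px beyond the fitted radius are discarded, and the angular-sorted
survivors are hulled and Bezier-smoothed. After smoothing, radii are clamped
to the fitted radius + outlier threshold so the pruning contract survives the
fit. Dilation radius and outlier threshold are config keys; 3 px each is
about a third of a typical wall thickness at challenge resolution.

### Epicardium: region-constrained dynamic programming

The ROI is resampled (bilinear, replicate outside) onto an M×N polar grid
about the endocardial centroid: row i ↔ radius i·Δr, column j ↔ angle 2πj/N,
defaults N = 180, Δr = 1 px. The radial extent is 2.5× the cavity's
equivalent radius, enlarged to cover the previous slice's epicardial extent
plus its dilation margin — in end-systole the wall is thick relative to the
small cavity and the cavity-based factor alone would truncate the target edge
into the masked boundary rows.

The edge feature is the gradient magnitude of the (lightly smoothed, σ = 1 px;
periodic in angle) polar image, thinned by non-maxima suppression along the
quantized gradient direction. Suppression keeps a pixel only if it is
strictly greater than one directional neighbor and ≥ the other: two-pixel
plateaus keep exactly one pixel and constant-slope ramps are erased entirely.
The first and last radius rows are resampling artifacts and are zeroed; the
result is min-max normalized to [0, 1].

Admissible positions B(i, j): at least one row beyond the endocardial radius
at that angle, not inside a bright region (pixels above the chosen blood-pool
threshold, dilated by 2 rows so suppressed-gradient ridges hugging a bright
boundary are excluded too), and inside the previous epicardial region dilated
by 3 (when a previous slice exists). A fully blocked column is reopened at
the two rows adjacent to the endocardial radius, so a feasible path always
exists — when the LVOT channel blanks a sector, the path detours along the
endocardium there rather than failing the slice.

The boundary is the minimum of Σⱼ w·(1 − F(iⱼ, j)) + γ·|i_N − i₁| over
paths with |iⱼ₊₁ − iⱼ| ≤ δ and |i_N − i₁| ≤ δ (defaults w = 1, γ = 0.1,
δ = 2). The closure penalty is made *exact* by running one DP sweep per
admissible first-column row (cost O(M²Nδ), trivial at these sizes) instead of
approximating the chain's first row from a single sweep. Every minimum —
predecessor choice, final row, start row — breaks ties toward the smaller row
index, which makes the optimum unique and lets a brute-force enumeration
oracle reproduce the path exactly, not just its cost.

### Smoothing

* **Endocardium:** radii about the centroid, resampled at the N working
  angles, pass through an ideal (brick-wall) low-pass DFT filter keeping the
  DC term plus 8 harmonics per side (configurable). The DC coefficient is
  untouched, so the mean radius is preserved exactly.
* **Epicardium (and the LVOT endocardium):** a closed piecewise-cubic fit.
  The curve is parameterized as a periodic uniform cubic B-spline — each span
  an exact cubic Bezier segment with C² (hence C1) joins — whose control
  points are solved by least squares against an arc-length resampling of the
  input polygon (16 segments, 180 output samples by default). On a circle the
  residual is ~0.004 px; applying the fit twice moves points < 0.05 px.

When both surfaces are final, epicardial radii are clamped to the endocardial
radius + 0.75 px at matched angles, so the myocardial annulus never
degenerates even after independent smoothing of the two contours.

## Orchestration

The mid slice (stack middle by default; overridable) is segmented first,
seeded by a centered circle of radius 15 px. Two independent marches then
proceed toward base (LVOT detection on) and apex (off), each passing the last
*successful* slice forward as context; a failed slice is recorded with its
failing stage and the march continues, which matches per-contour scoring of
the challenge datasets. A mid-slice failure aborts the study (there is no
context to propagate). Slices whose pool shrinks below 20 px are marked
`skipped_small_pool` — the apical pool genuinely vanishes and forcing a
contour there produces noise. ED and ES stacks are processed independently
with identical parameters. The pipeline contains no randomness: identical
input and config reproduce contours bit for bit.

## Evaluation conventions

* APD is one-directional, automatic → expert, averaged over the automatic
  contour's points (point-to-segment distances against the expert polyline);
  a symmetric variant is available but off by default.
* "Good" means APD < 5 mm, strictly; summary APD/Dice are reported over good
  contours only in the CLI report.
* Volumes are slice summations: enclosed polygon (shoelace) area × pixel
  area × center-to-center slice spacing. Myocardial density is 1.05 g/mL.
* Bland–Altman limits use ±1.96 sample standard deviations (ddof = 1) of the
  paired differences.

## The phantom, and what passing tests do not show

The synthetic study emulates the features the method actually keys on: a
bright cavity (200) in a darker myocardial annulus (60) on a brighter
background (80) — the myocardium/background contrast deliberately weaker than
the myocardium/pool contrast — an adjacent bright RV crescent and a
pericardial fat arc (the structures the DP mask must exclude), linear radius
taper base→apex, a 0.7× end-systolic cavity (closed-form EF = 51 %), additive
Gaussian noise (σ = 8, i.e. pool/myocardium contrast-to-noise ≈ 17) and a
±10 % multiplicative polynomial bias field, with a small per-slice center
drift to exercise ROI tracking. The optional basal LVOT channel is a bright
wedge breaching the wall, sized so the hull major-axis ratio exceeds the
detection threshold by construction. Analytic volumes use the same
stacked-disk quadrature as the evaluation module (Σ πr²·pixel-area·spacing),
so EF and LVM have closed forms the evaluation must reproduce within
discretization error.

The phantom does **not** simulate Rician noise statistics, partial-volume
blur at tissue interfaces, papillary-muscle texture inside the cavity, motion
or flow artifacts, through-plane misalignment between slices, or anatomical
shape variability (the truth is circular by construction). Passing the suite
demonstrates the algorithm's correctness and its robustness to noise, bias
and the modeled confounders — not clinical-grade accuracy on patient data,
which requires evaluation against expert contours on real studies.

## Problem sizes used by the test suite and acceptance script

Chosen to exercise every code path at full fidelity while staying desk-scale:
the DP/enumeration comparison uses 200 random 5–8 × 6–10 maps (δ ∈ {1,2},
γ ∈ {0, 0.5}) drawn on a dyadic 1/64 grid so costs are exact in floating
point and tie-breaks are reproducible; the level-set recovery uses 20 seeded
80×80 noisy biased disks; the end-to-end runs use the default 8-slice,
two-phase, 128×128 phantom (with and without LVOT), segmented twice for the
determinism check.

## Known limitations

* ES epicardial truth exists in the phantom, but challenge datasets omit
  expert ES epicardial contours; the evaluation CLI simply scores whatever
  pairs are present.
* DICOM phase handling is frame-index based (earliest trigger = ED; ES frame
  given explicitly); automatic ED/ES detection from the cine loop is out of
  scope.
* The DP assumes the epicardium is star-shaped about the endocardial
  centroid (one radius per angle) — true for short-axis LV anatomy, not for
  arbitrary shapes.
* Threshold search assumes the pool is brighter than myocardium; inverted
  contrast (e.g. some gradient-echo artifacts) is not handled.
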