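# Methods

`coroseg` extracts vessel centerlines from 2D X-ray coronary angiograms in
four stages: contrast restoration, multiscale tube enhancement,
region-based segmentation, and adaptive centerline tracking with
bifurcation detection. Because clinical angiograms with ground truth are
rarely available, the package validates itself on synthetic tubular-tree
phantoms whose centerlines, widths, masks and forks are known analytically.
This note records the models, the parameters that matter, the numerical
choices, and what the phantom validation does and does not demonstrate.

## Preprocessing

**Collaborative block-matching denoising** (`preprocess.denoise`).
Overlapping 8×8 patches are grouped with their most similar neighbors
inside an 11×11 search window (L2 patch distance via integral images), the
group is transformed with a 2D DCT per patch plus a 1D DCT across the
group, coefficients below `threshold_factor * noise_sigma` (default 2.7 σ)
are zeroed, and the filtered patches are aggregated back with weights
proportional to the inverse retained-coefficient count. The group-mean
coefficient is never thresholded, so constant images pass through exactly.
`noise_sigma` is the assumed additive-noise standard deviation on the
[0, 255] scale; 0 disables the stage bit-exactly. On the noisy phantom
(σ = 15) the residual error after this stage is ≈ 2.2 gray levels.

**Unsharp masking** (`preprocess.unsharp_mask`): `g = I + k (I − mean_n(I))`
with an n×n mean filter (default n = 9, replicate borders) and enlarge
coefficient k (default 0.8). **CLAHE** (`preprocess.clahe`): per-tile
(8×8 grid, 256 bins) histograms clipped at `clip_limit` (default 1.5)
times the uniform bin height, excess redistributed equally and re-clipped
(≤ 16 rounds, mass conserved), CDF mappings interpolated bilinearly
between tile centers. The two defaults are deliberately at the mild end of
the conventional ranges: the stages multiply as noise amplifiers
(≈ (1+k) · clip on the denoising residual), and the tracker's fixed
intensity floor I0 = 10 (see below) requires the enhanced background to
stay below ≈ 4 % of full scale. At k = 1.5 / clip = 2.5 the enhanced
background of the noisy phantom reaches the 19/255 percentile level and
85 % of detected ridge points are spurious; at 0.8 / 1.5 the background
stays at 6/255 with 95 % of ridge points on-vessel, while the vessel
response is essentially unchanged.

## Multiscale vesselness

Tube-likeness is scored from the eigenvalues |λ1| ≤ |λ2| of the Gaussian
Hessian at scale σ:

    V(σ) = 0                                   if λ2 ≥ 0
    V(σ) = exp(−R_B² / 2β²) · exp(−2m² / λ2²)
           · (1 − exp(−S_H² / 2c²))            otherwise

with R_B = |λ1|/|λ2| (blobness) and S_H = √(λ1²+λ2²) (structure).
Defaults β = 0.5, c = 20, σ ∈ {1,…,10} (10 scales). The m-factor is kept
exactly in this printed form; its default m = 0 makes it neutral, and
whether the intended exponent was −λ2²/(2m²) is left open rather than
guessed. Derivatives are γ-normalized (× σ^γ, default γ = 2) so the
per-pixel maximum over scales is comparable; without normalization the
multiscale maximum is meaningless. For a Gaussian profile of standard
deviation s the γ = 2 argmax is at σ = √2 s, so a 3 px-std bar selects
integer scale 4 — within one scale step of the profile width. Because the
score zeroes where λ2 > 0 it enhances *bright* tubes; dark-vessel
angiograms (the default polarity) are inverted (255 − I) first.

Discrete detail: the sampled Gaussian derivative kernels are
moment-corrected (smoothing kernel sums to 1, second-derivative kernel has
exactly zero sum and second moment 2), so constants map to exactly zero
response and quadratics to their exact second derivative; the raw sampled
kernels miss both by O(10⁻³), which matters because downstream tests
compare eigenvalue signs near zero. The response is max-normalized to
[0, 255]; a structureless image (max raw score < 10⁻⁹) maps to zeros
instead of having numerical noise stretched to full range.

## Chan–Vese segmentation

The two-phase piecewise-constant energy

    F = u·L(C) + v·S_b(C) + λ0 ∫_outside (I − c0)² + λb ∫_inside (I − cb)²

is minimized over a level-set field w (w > 0 inside) with the smooth
Heaviside H_ε(w) = ½(1 + (2/π) arctan(w/ε)). Defaults: u = 0.2·255²,
v = 0, λ0 = λb = 1, ε = 1.5, dt = 0.5, up to 1500 iterations, tol = 1e−5.
The paper's adaptive rebalancing of λ0/λb ("enlarge λ0 to accelerate") is
guidance without a rule and is not implemented; the weights are constant
and exposed in config.

Numerics. The update is the canonical semi-implicit scheme: the curvature
term is treated implicitly through half-point coefficients, the fit terms
explicitly, both gated by the smoothed delta; the image is worked on a
[0, 1] scale and the initial field normalized to unit amplitude. A plain
explicit step at these weights is unstable by orders of magnitude (it
collapses a checkerboard init into the absorbing all-inside state), and
periodic signed-distance reinitialization deadlocks the scheme: rebuilding
|w| to true distances shuts the delta gate far from the interface, so
wrongly-labelled background can never flip. Reinitialization is therefore
off by default (`reinit_every = 0`, available in config), matching the
canonical implementations, and w stays O(1) on its own. The checkerboard
init uses a 10 px period — fine enough for fast, init-insensitive global
relaxation. scikit-image's `chan_vese` (the same scheme) is used as an
independent cross-check in the test suite, never as the implementation.

The recorded energy history reports each iterate's *partition* energy,
measured on its signed-distance representative: on the bounded evolving
field the δ-smeared length/fit proxies conflate parametrization drift with
contour motion (a spurious mid-run rise of several percent). The stopping
test uses the smoothed-field energy, which changes continuously. The final
sign of w is oriented so "inside" is the brighter phase; the energy itself
is label-symmetric. Masks are {w > 0}; contours come from marching squares
on the zero level.

On the enhanced noiseless tube the converged mask matches the analytic
tube to Dice 0.97, and a noiseless disk to Dice 1.00 from either init. On
the Y-tree the energy's own minimum is a band ≈ 0.4 px wider than the
analytic tube plus a bulge at the fork (Dice ≈ 0.86–0.89); the reference
implementation lands on the same partition, so this reflects the model,
not the solver.

## Ridge points

A pixel is a ridge point when (a) the image gradient changes sign across
the pixel cell — the dot product of the gradients at either diagonal
corner pair is negative (or exactly zero with a non-zero corner gradient:
a pixel-centered symmetric crest makes the product vanish instead of
changing sign), (b) the cross-vessel eigenvalue λ2 is negative at all four
cell corners, and (c) the enhanced intensity exceeds `gray_threshold`
(default 10, shared with the tracker's floor). The along-vessel eigenvalue
λ1 is *not* constrained: a ridge point is the transverse intensity
maximum, and on an ideal tube crest λ1 is identically zero, its sign
decided by discretization noise — constraining it makes clean tubes
undetectable. Eigen-structure is taken at each pixel's best scale.

Scattered points are pruned in a single pass: a point survives only if at
least τ_R = 3 *other* ridge points lie within `neighborhood_radius_R`
(default 3 px — at 2 px the filter erodes the sparse ends of genuine
chains, defeating its purpose; isolated speckle has 0–1 neighbors either
way).

## Adaptive tracking

From a uniformly random ridge seed: the forward direction points to the
interpolated-intensity maximum on the circle of radius d (default 5 px,
1° sampling, bilinear interpolation, ties to the smallest angle); the
backward search arc is centered on the true opposite direction θ⁺ + 180°
(the printed 2π − θ⁺ is a mirror, contradicted by the surrounding text and
figure). Each step searches the forward arc (±Δθ = 45°) of radius d and
accepts the maximum if its intensity exceeds I0 = 10 (vessel-end guard)
and fewer than τ_P = 4 accepted points lie within `np_radius` (= d) of it
(loop guard). The step direction is u_k = (P_k − P_{k−1})/‖·‖; the printed
reversed difference would make every arc search retrace the path.

Every accepted point is re-centered: rays along ± the trajectory normal
(0.25 px sub-steps, capped at `max_ray` = 20 px) find the two segmentation
contour crossings by linear interpolation of the mask edge, and the point
moves to the chord midpoint; if the point is outside the mask or a ray
finds no crossing, it is left in place and flagged. A displacement below
d/2 leaves the direction untouched — at a branch anchor the previous point
coincides with the current one and the tiny adjustment vector carries no
direction information.

Bifurcations are sought at every accepted point in the fan ring r ∈ [7, 12]
px, ±135° around the current direction; a ridge point qualifies if its
bearing differs from the current direction by more than τ1 = 45° and from
the previous direction by more than τ2 = 30°, lies farther than d, and
fewer than τ_B = 2 accepted bifurcations lie within `nb_radius` (= r2) of
it. The brightest qualifying candidate becomes the branch point and its
branch is tracked FIFO, one-directionally away from the parent. All
constants are the published set; tracking stops globally at `max_points`
(default 5000).

Known limitation (measured, by construction): the detected branch point is
a ridge point of the *new branch*, not the junction. The ring starts at
r1 = 7 and the fan excludes backward bearings, so the nearest admissible
candidate sits ≥ 6.5 px from the fork even with perfect ridge maps; with
the junction dimming of the blobness factor and the brightest-candidate
rule the measured localization is ≈ 9 px. Topology (which branches exist,
where they run) is unaffected.

## Phantoms and metrics

Phantoms are quadratic Bézier branches with Gaussian cross-sections
(σ_profile = half-width / 2), linear width and contrast taper, combined by
per-pixel maximum over a background with optional linear illumination
gradient and seeded additive Gaussian noise; polarity chooses bright or
dark vessels. Ground truth (0.5 px centerline polylines, local widths,
tube mask = {distance ≤ local half-width}, fork points where ≥ 3 branch
endpoints coincide) comes from the curves, never from the image. The
canonical set: a straight tube (256², half-width 3, contrast 120 over 30),
an S-tube, a Y-tree (trunk half-width 3.5 → 3.0, daughters 3.0 → 2.25 and
contrast 120 → 80, each daughter 40° off the trunk axis), and the same
Y-tree with σ = 15 noise, an illumination gradient and dark polarity.
Two deliberate realism choices double as numerical hygiene: branches taper
in width and contrast (distal contrast loss is characteristic of real
angiograms, and a constant tube leaves the along-vessel eigenvalue at
exact zero, which no sign test can read), and preset axes sit 0.3 px off
the pixel grid (exact alignment zeroes the transverse crest gradient
identically — another measure-zero degeneracy real data never shows).

Metrics: `centerline_error` reports the mean distance of tracked points to
the truth, the fraction of truth points within 2 px of the tracked *curve*
(branch polylines resampled at 0.5 px — points are d apart and a dotted-
line reading would cap coverage at 80 % for a perfect track), and the
symmetric Hausdorff distance. `bifurcation_score` merges detections closer
than the tolerance into centroids, then matches greedily one-to-one.

What the phantoms do not exercise: cardiac motion blur, catheter and rib
artifacts, vessel crossings and foreshortening, structured (non-Gaussian,
spatially correlated) X-ray noise, and vessel-width ranges beyond a few
pixels. Passing the suite shows the pipeline is internally correct and
robust to additive noise and slow illumination changes at desk scale, not
that it matches clinical performance.

## Problem sizes

All validation images are 256² (disk tests 128²); the tracker handles a
few hundred points per tree; Chan–Vese needs 50–1400 semi-implicit
iterations depending on structure thinness. The full validation battery
(`scripts/acceptance.py`) renders every phantom, runs the complete
pipeline and reports its measurements in about one minute on one CPU.
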