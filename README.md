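# coroseg

Vessel enhancement, segmentation and automatic centerline extraction for
2D X-ray coronary angiograms.

Coronary angiography images contrast-filled arteries as dark curvilinear
structures on a bright, noisy background. Finding the vessel tree —
its contours, its centerlines, and where it branches — is the groundwork
for downstream tasks such as stenosis assessment, and doing it by hand is
slow and subjective. `coroseg` implements a classical pipeline for this
problem:

1. **Preprocessing** — collaborative block-matching denoising, unsharp
   masking `g = I + k(I − Ī)`, and contrast-limited adaptive histogram
   equalization;
2. **Multiscale Hessian vesselness** — with Hessian eigenvalues
   |λ1| ≤ |λ2|, the tube-likeness
   `V = exp(−R_B²/2β²)·exp(−2m²/λ2²)·(1 − exp(−S_H²/2c²))` for λ2 < 0
   (else 0), where `R_B = |λ1|/|λ2|` and `S_H = √(λ1²+λ2²)`, maximized
   over scales σ ∈ [1, 10];
3. **Chan–Vese segmentation** — minimization of the two-phase energy
   `u·L(C) + v·S_b(C) + λ0∫(I−c0)²(1−H(w)) + λb∫(I−cb)²H(w)` over a
   level-set field `w`, yielding the vessel mask and contour;
4. **Adaptive tracking** — from a random ridge-point seed, repeated
   arc searches of radius `d` (±Δθ) on the enhanced image, with
   intensity and loop guards, contour-based re-centering of every point,
   and fan-ring bifurcation detection (radii r1–r2, half-angle Δθ′,
   angle-gap thresholds τ1/τ2) that spawns new branches until the tree
   is exhausted.

Validation is phantom-driven: a built-in generator renders tubular-tree
images (Gaussian cross-sections, width/contrast taper, illumination
gradients, seeded noise) with exact analytic ground truth, and all
quantitative claims in the test suite are made against those phantoms.
See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
import numpy as np
from coroseg.phantom import y_tree_spec, render_phantom, centerline_error
from coroseg import PipelineConfig, run_pipeline

spec = y_tree_spec()                      # noiseless bright Y-tree, 256x256
img, truth = render_phantom(spec)
cfg = PipelineConfig(vessel_polarity="bright", enable_denoise=False,
                     enable_unsharp=False, enable_clahe=False, rng_seed=4)
res = run_pipeline(img, cfg)
m = centerline_error(res.skeleton, truth)
print(f"ridge points:   {len(res.ridges_filtered)}")
print(f"branches:       {len(res.skeleton.branches)}")
print(f"track points:   {res.skeleton.n_points}")
print(f"bifurcations:   {len(res.skeleton.bifurcations)}")
print(f"coverage:       {m['coverage']:.3f}")
print(f"mean distance:  {m['mean_dist']:.2f} px")
```

prints

```
ridge points:   342
branches:       5
track points:   109
bifurcations:   4
coverage:       0.982
mean distance:  0.35 px
```

Reading: 342 centerline (ridge) pixels survive screening; tracking from
one random seed reconstructs the tree as 5 branch traversals (re-tracked
segments are stopped by the loop guard) totalling 109 points; 4 fan-ring
detections cluster at the single true fork — each is a ridge point of the
newly found branch, so they sit a few pixels distal of the geometric
junction (see `docs/methods.md`); 98.2 % of the true centerline lies
within 2 px of the tracked curve, and tracked points sit 0.35 px from the
true centerline on average.

## Command line

```sh
coroseg phantom --spec examples/phantom_y.yaml --outdir out/    # image + truth
coroseg run out/image.png --config examples/config.yaml --outdir out/run
coroseg eval --skeleton out/run/skeleton.json --truth out/truth.json
```

Per-stage subcommands (`preprocess`, `segment`, `track`) expose the
intermediate outputs; all parameters live in a flat YAML config in which
every key is optional (`examples/config.yaml`).

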