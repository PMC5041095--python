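# Methods

## Problem

Dynamic contrast-enhanced (DCE) MRI of the liver acquires the same slice
repeatedly before and after contrast-agent injection. Pharmacokinetic
analysis needs every voxel to correspond to the same tissue across frames,
but breathing and imperfect breath holds move the organ by several pixels,
while the contrast agent changes intensities by tens of percent in exactly
the structures of interest. Plain intensity-based registration confuses the
two effects and characteristically shrinks or inflates enhancing structures
(tumor rims, vessels).

`geodereg` addresses this with three cooperating ideas:

1. **De-enhancement by robust PCA.** The frames, vectorized as columns of an
   m×n matrix M, are split as M = L + S with L low-rank and S sparse by
   solving min ‖L‖\* + λ‖S‖₁ s.t. M = L + S. Motion is slow and global
   (low-rank); enhancement is fast and spatially confined (sparse).
   Deformations are estimated on the re-folded low-rank frames and applied
   to the originals.
2. **A manifold of frames.** Frames are nodes of a kNN graph weighted by the
   residual-complexity (RC) dissimilarity, with k the smallest value that
   connects the graph. Each frame registers to the geodesic-mean template
   hop-by-hop along its graph-geodesic path, so one large deformation
   becomes a chain of small deformations between genuinely similar images.
3. **Iteration with a growing sparsity trade-off.** λ = C_t/√max(m,n) with
   C_t geometric across outer sweeps, so early sweeps de-enhance
   aggressively and later sweeps refine on nearly raw intensities.

## Components and numerical choices

### RPCA (inexact ALM)

One SVD of the thin m×n matrix per iteration; singular-value shrinkage for
L, entrywise soft-thresholding for S. Schedule: μ₀ = 1.25/σ₁(M), geometric
growth ρ (default 1.6), dual init Y₀ = M / max(σ₁, ‖M‖∞/λ); stop when
‖M−L−S‖_F/‖M‖_F ≤ 1e−7 (cap 500 iterations, non-convergence flagged, not
raised). The fast default ρ reaches feasibility quickly but can stop ~1e−2
short of the convex optimum; ρ is exposed, and ρ ≈ 1.05 with a tight
tolerance tracks the optimum to ~1e−10 when solver-grade accuracy is wanted
(the test suite's exact-ALM oracle comparisons run that way). A caution
for phantom designers: at desk-scale matrix sizes (e.g. 60×20) the
exact-recovery phase boundary is nearby — whether the planted (L₀, S₀) is
the argmin depends on the instance, not the solver.

### Residual complexity

RC(a,b) = Σ log(1 + c²/α), c = orthonormal 2-D DCT of a−b, α = 0.05. Smooth
intensity distortion (the contrast agent's signature at organ scale)
concentrates into few coefficients and scores low; misalignment spreads
energy and scores high. The orthonormal DCT normalization is fixed so that a
constant residual v on N pixels gives exactly log(1 + Nv²/α). The analytic
gradient ∂RC/∂b = −IDCT(2c/(α+c²)) drives the optimizer. No intensity
pre-normalization is applied inside the metric.

### Manifold

Pairwise RC is computed on the original (current, warped) frames — not the
low-rank frames, which intentionally discard part of the signal. kNN edges
are union-symmetrized (edge if either endpoint lists the other), which makes
connectivity monotone in k, so the smallest connecting k is found by a
linear scan with a BFS check. All-pairs geodesics by repeated Dijkstra; all
ties (neighbor lists, path choice, template argmin) break toward the
smallest node index / lexicographically smallest node sequence so runs are
bit-reproducible. Paths are computed for i<j with the lexicographic
tie-break and reversed for j>i; when several geodesics tie, the reverse
convention wins over per-direction lexicographic minimality. The template is
the node with the minimal summed geodesic distance.

### FFD registration

Cubic tensor-product B-spline control grid; backward (pull-back) mapping
convention everywhere: a field u sends fixed-grid coordinates x to
moving-frame coordinates x+u(x), resampled bilinearly with edge clamping.
Coordinates are 0-based pixel-centered (row, col); displacements in pixels.
Three pyramid levels (×4, ×2, ×1) with control spacing 32→16→8
full-resolution pixels (8 px at each level's own grid); L-BFGS with the
analytic RC gradient chained through the B-spline basis; stop at relative
cost change < 1e−5 or 100 iterations per level; coarse solutions transfer by
realizing the field, upsampling, and least-squares refitting the finer grid.
Composition u_comp(x) = u_inner(x) + u_outer(x + u_inner(x)) matches
sequential warping; per-frame totals are right-to-left compositions along
the geodesic path starting from the template-adjacent edge.

A light bending-energy penalty on the control lattice (weight 0.1 on the
squared second differences) is on by default. The package's phantom studies
showed why: with no regularization, a motion-free but enhancing phantom
acquires +6% spurious tumor volume change and up to 4 px of spurious
deformation — enhancement that leaks into the low-rank frames is happy to
masquerade as deformation, and nothing else restrains an 8-px-spacing FFD.
Weight 0.1 removes that pathology entirely while leaving 4-px synthetic-warp
recovery at 0.23 px mean error. Set `bending_weight: 0` to reproduce the
unregularized behavior.

### Outer loop

Defaults: 2 sweeps, C_t = 5^(t/3) (so four sweeps would span the 1→5 log
grid). The iteration study on default phantoms showed liver-mask endpoint
error converging by sweep 2 (≈0.3 px) while tumor volume drift accumulates
roughly linearly with every further sweep (+3% → +6% between sweeps 2 and
4); two sweeps take both the accuracy and the topology-preservation optimum.
The manifold is rebuilt every sweep on the current warped frames; the
template is frozen after the first sweep (`template_policy:
fixed-after-first`) because a drifting reference makes convergence
unmeasurable; `recompute` is available. Only edges actually used by some
geodesic path are registered — unused edges never enter a composition.

## The phantom

`PhantomSpec()` emulates a single-slice liver DCE acquisition at desk scale:
128×128 px, 22 frames, 6 pre-contrast. Geometry: body and liver ellipses, a
15-px tumor (≈3–4 cm lesion at clinical resolution) with a 4-px enhancing
rim and weakly enhancing core, three vessels. Enhancement is a truncated
logistic per tissue — exactly zero before bolus arrival (so pre-contrast
normalized TICs are exactly 1), then amplitude/(1+exp(−rate·(t−onset))) —
with vessels early/strong, liver moderate, rim enhancing, core weak.

Intensities are a piecewise-constant tissue map modulated by a fixed
multiplicative texture field (Gaussian-filtered noise, σ = 2 px, 20%
amplitude). Texture matters twice over: it gives registration something to
lock onto away from tissue boundaries (without it, recovery of a known 4-px
warp plateaus at ~1.2 px for RC and SSD alike), and being multiplicative and
constant in time it cancels exactly in baseline-normalized TICs, so the
stored per-tissue truth curves (b + e(t))/b are exact for any ROI inside one
tissue.

Motion is a bulk per-frame translation random walk (breathing) plus a
0.4-fraction local B-spline wobble, anchored at frame 0 and scaled to a
2.5-px maximum; two seeded jump frames add a transient translation-dominated
shift up to 2× (mistimed breath holds). Noise is Gaussian (σ = 0.01 in unit
intensities; a Rician switch exists). The generator returns the exact
per-frame displacement fields, binary masks and clean curves.

What the phantom does **not** model: through-plane motion, pulsation,
partial-volume fat/water effects, spatially varying coil sensitivity, true
pharmacokinetics (curves are intensity-level logistics, not concentration
models), and rater variability in ROI placement. Passing phantom tests
therefore demonstrates the machinery — de-enhancement, geodesic
decomposition, topology preservation, TIC recovery — under known truth, not
clinical performance.

## Evaluation battery

* **TICs**: an ROI is a marked pixel plus its 9 most similar neighbors in a
  5×5 window, ranked by pre-contrast intensity difference then distance then
  (row, col) — a deterministic stand-in for the expert rule of picking
  points with similar contrast uptake. `rim_roi_seeds` picks deterministic
  mid-rim seed pixels (per-sector distance-transform argmax). Curves are
  normalized by the mean of the pre-contrast per-frame means (reduces to the
  single-pre-frame convention when n_pre = 1) and compared by RMSE on the
  normalized scale.
* **Volume change**: 100·(V_post − V_pre)/V_pre, with the tumor mask carried
  into each observed frame by the true motion and back through the recovered
  field by nearest-neighbor resampling, then counted. At 128² this counting
  carries ±2% quantization noise — the phantom's lesion size was chosen so
  that this noise stays well under the effects being measured.
* **Endpoint error** (phantom only): the anatomical position reached through
  the recovered field vs. the template's anatomical position, averaged over
  the liver+tumor+vessel mask with a 10-px border margin.
* **Jacobian positivity** of composed fields (central differences) as the
  topology-preservation check; subtraction and time-cut images for visual
  inspection.

## Problem sizes

Unit and acceptance tests run at the generator's native desk scale (128×128,
22 frames; 64–96 px variants for orchestration-level checks), with 5
generator seeds for the ordering studies and 20 seeds for the combinatorial
oracles. These sizes were chosen so the full suite exercises every component
end-to-end in minutes on one CPU; clinical 320×320 series run through the
identical code path via `PhantomSpec(shape=(320, 320))` or `read_series`.

## Known limitations

* The sparse RPCA term does not capture enhancement that is itself low-rank
  (a fixed spatial pattern times a smooth curve); residual enhancement in L
  is expected and is why the bending penalty and small geodesic hops matter.
* Long geodesic paths (5–6 hops) accumulate per-hop bias; the two-sweep
  default and the regularizer bound it, but template positions at the
  temporal margin of a series remain the hardest case.
* With the default regularized FFD, the direct-to-template comparator is
  also largely protected on mildly enhancing phantoms; the dramatic
  direct-registration volume distortion appears when `bending_weight: 0`.
* 2-D per-slice only, by design; multi-slice stacks are processed
  independently.
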