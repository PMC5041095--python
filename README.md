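# geodereg

Motion correction for dynamic contrast-enhanced (DCE) MRI time series —
built for the liver, where contrast-agent uptake changes intensities in
exactly the structures that must not be deformed. Plain intensity-driven
registration mistakes enhancement for motion and shrinks or inflates tumor
rims and vessels; `geodereg` separates the two effects and registers along
a manifold of frames instead of jumping straight to a reference.

The method, in one paragraph: the n frames are stacked as columns of a
matrix M and split by robust PCA, M = L + S (solve min ‖L‖\* + λ‖S‖₁ s.t.
M = L + S, λ = C/√max(m,n), by inexact augmented Lagrange multipliers) —
the low-rank part L carries anatomy and motion, the sparse part S carries
enhancement. A kNN graph over the frames, weighted by residual complexity
RC(a,b) = Σ log(1 + c²/α) with c the 2-D DCT of a−b, approximates the
manifold the series lives on; k is the smallest value that connects the
graph. The template is the geodesic-mean frame (minimal summed graph
distance), and every frame reaches it hop-by-hop along its Dijkstra
geodesic, each hop a cubic B-spline free-form deformation minimizing RC on
the *low-rank* frames. The per-hop fields are composed into one field per
frame, the *original* frames are warped, and the whole cycle repeats with
λ growing geometrically. Ground-truth evaluation (time–intensity-curve
RMSE, tumor volume change, endpoint error, Jacobian positivity) comes from
a synthetic liver phantom with exact per-frame displacement fields.

Audience: image-analysis researchers and methods developers working on
DCE-MRI preprocessing who need a tested, reproducible 2-D+t registration
baseline with a fully instrumented synthetic benchmark.

## Worked example

```python
import numpy as np
from geodereg import PhantomSpec, generate, run
from geodereg.evaluation import (endpoint_error, make_roi, extract_tic,
                                 tic_rmse, rim_roi_seeds,
                                 transported_tumor_volume_change)
from geodereg.ffd import warp

truth = generate(PhantomSpec(seed=1))      # 22 frames, 6 pre-contrast, 128x128
res = run(truth.observed_series)           # full manifold-geodesic pipeline
T = res.template_index

organs = truth.masks["liver"] | truth.masks["tumor"] | truth.masks["vessel"]
epe = [endpoint_error(f, truth.true_fields[i], truth.true_fields[T], organs)
       for i, f in enumerate(res.per_frame_total_field)]
print(f"template frame {T}, mean endpoint error {np.mean(epe):.2f} px")

rim = warp(truth.masks["tumor_rim"].astype(float),
           truth.true_fields[T], order=0).astype(bool)
before, after = [], []
for seed_px in rim_roi_seeds(rim):          # four mid-rim ROIs
    before.append(tic_rmse(
        extract_tic(truth.observed_series,
                    make_roi(truth.observed_series, seed_px)).normalized,
        truth.true_tics["tumor_rim"]))
    after.append(tic_rmse(
        extract_tic(res.warped_series,
                    make_roi(res.warped_series, seed_px)).normalized,
        truth.true_tics["tumor_rim"]))
print(f"tumor-rim TIC RMSE (median of {len(before)} ROIs): "
      f"{np.median(before):.3f} unregistered -> {np.median(after):.3f} registered")
print(f"tumor volume change "
      f"{transported_tumor_volume_change(res.per_frame_total_field, truth):+.2f}%")
```

prints

```
template frame 16, mean endpoint error 0.26 px
tumor-rim TIC RMSE (median of 4 ROIs): 0.145 unregistered -> 0.038 registered
tumor volume change +2.92%
```

i.e. on this phantom the recovered deformations land within a quarter pixel
of the truth inside the liver, the fixed-ROI tumor-rim intensity curve
tracks the true uptake more closely after registration, and the tumor's
apparent volume across contrast arrival changes by under 3% (the
topology-preservation goal; unconstrained registration of enhancing
structures typically distorts far more).

The same pipeline runs from the shell:

```bash
geodereg simulate --seed 1 --outdir sim/            # phantom + ground truth
geodereg run --input sim/observed.nii.gz --n-pre 6 --outdir reg/
geodereg baseline --input sim/observed.nii.gz --n-pre 6 --outdir base/
geodereg evaluate --input reg/warped.nii.gz --n-pre 6 --roi 69 55 --outdir eval/
geodereg rc sim/clean.nii.gz sim/clean.nii.gz       # prints 0
```

`run` writes the warped stack, per-frame displacement fields (NIfTI), the
manifold as JSON, a JSON-lines iteration log and a manifest that makes the
run bit-reproducible. `baseline` is the direct-to-template comparator
(identical loop, no geodesic decomposition).

## Layout

| module | contents |
| --- | --- |
| `geodereg.rpca` | series matrix, λ rule, inexact-ALM solver |
| `geodereg.similarity` | residual complexity and its analytic gradient |
| `geodereg.manifold` | pairwise RC, smallest connecting k, Dijkstra geodesics, template |
| `geodereg.ffd` | B-spline transforms, warping, composition, Jacobians, pairwise registration |
| `geodereg.pipeline` | the outer loop (`run`) and the comparator (`direct_baseline`) |
| `geodereg.phantom` | synthetic DCE liver generator with exact ground truth |
| `geodereg.evaluation` | TICs, volume change, endpoint error, subtraction/time-cut images |
| `geodereg.io`, `geodereg.cli` | NIfTI/TSV/JSON I/O, manifests, the `geodereg` command |

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.
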