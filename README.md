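# mrdistcorr

Phantom-based mapping and correction of 3D **system-related geometric
distortion** in MR images — gradient nonlinearity and residual B0
inhomogeneity displace structures by several millimetres toward the edge of
the field of view, which matters wherever MR geometry is trusted
quantitatively (MRI-only radiotherapy planning being the canonical case).

The method images a grid-sheet phantom (17 styrene sheets, 17×17 bar
crossings each, 15 mm pitch) in CT — taken as distortion-free *world*
coordinates — and in MR in three orthogonal orientations, each with forward
and reversed read gradient.  The pipeline:

1. **Control-point extraction** — per-slice unsharp masking, an adaptive
   per-slice threshold, and a directional line-crossing detector locate
   every grid crossing with sub-voxel precision, robust to intensity
   inhomogeneity, noise and air bubbles.
2. **Registration** — CT and MR point sets are brought into the common
   isocenter frame (translation only), artifact points are rejected with a
   per-sheet third-order polynomial fit, and one-to-one CT↔MR pairs are
   formed.  Forward/reverse positions are averaged to cancel the
   B0-induced shift: x = (x_fwd + x_rev)/2.
3. **Field estimation** — each acquisition measures the in-plane
   displacement components, giving a double estimate per axis,
   δx⁰ = (δx_tra + δx_cor)/2 etc.  Because in-plane values are housed at
   *apparent* through-plane positions, this first-order estimate is biased
   under through-plane field gradients; the **iterative refinement**
   re-evaluates each component at coordinates displaced by the latest
   estimates of the others, δxⁿ(x, y + δyⁿ⁻¹, z + δzⁿ⁻¹), until every
   per-point change falls below a cutoff φ (default 0.2 mm) — typically
   2–4 passes.
4. **Correction** — the converged samples are interpolated into a
   continuous cubic-spline map δ(x) and each distorted volume is resampled
   at x + δ(x); re-running the whole pipeline on the corrected volumes
   measures the residual distortion, the method's figure of merit.

A built-in simulator renders the phantom with exact partial-volume
coverage, warps it with a known analytic degree-3 field (max ≈ 5.5 mm over
the control-point volume), and adds bias, noise, air bubbles and a
polarity-signed B0 shift — so every stage is validated against ground
truth without scan data.  See `docs/methods.md` for the model details and
numerical choices.

## Worked example

The full synthetic study — the 17-sheet phantom at half resolution
(1.8×1.8×2 mm), the default ~5.5 mm field, 30% bias, 5% noise and 10 air
bubbles, three orientations with forward/reverse gradients — runs in about
six minutes:

```python
import logging
logging.disable(logging.WARNING)

from mrdistcorr import StudyConfig, run_study

config = StudyConfig(voxel_mm=(1.8, 1.8, 2.0), bias_amplitude=0.3,
                     noise_sigma=45.0, bubble_count=10,
                     correct="iterative", seed=20260923)
result = run_study(config)
report = result["report"]
print("points matched per orientation:",
      {k: v["matched"] for k, v in report["counts"].items()})
print("iterations:", report["n_iterations"], "converged:", report["converged"])
found = report["stats_iterated"]["table"]["r"]
resid = report["residual_iterative"]["table"]["r"]
print(f"distortion found  (dr): mean {found['mean_mm']:.2f} mm, max {found['max_mm']:.2f} mm")
print(f"residual after fix (dr): mean {resid['mean_mm']:.2f} mm, max {resid['max_mm']:.2f} mm")
```

prints

```
points matched per orientation: {'transverse': 4913, 'sagittal': 4913, 'coronal': 4909}
iterations: 2 converged: True
distortion found  (dr): mean 1.79 mm, max 5.28 mm
residual after fix (dr): mean 0.16 mm, max 0.53 mm
```

Essentially all 4913 control points are matched in every orientation
despite bias, noise and bubbles; the mapped distortion (mean 1.79 mm, max
5.28 mm) collapses after correction to a residual far below the voxel
size.  Statistics are reported over the analyzed volume of interest (the
outermost sheet on each side of the stack is excluded; its single-sided
sampling makes estimates there unreliable).

## Command line

```bash
mrdistcorr simulate --voxel 1.8 1.8 2.0 --seed 1 --out study/      # synthetic study + ground truth
mrdistcorr extract --in study/mr_tra_fwd.nii.gz --modality mr \
    --orientation transverse --polarity forward --out tra_fwd.csv
mrdistcorr register --ct ct_points.csv --mr mr_points.csv --out pairs_tra.csv
mrdistcorr map --tra pairs_tra.csv --sag pairs_sag.csv --cor pairs_cor.csv \
    --phi 0.2 --out field/
mrdistcorr correct --in vol.nii.gz --field field/field_iterated.csv --out vol_corr.nii.gz
mrdistcorr run --out studyrun/            # the whole pipeline in one go
```

Volumes are read and written as NIfTI-1 or DICOM series; point sets, pairs
and field samples as CSV.

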