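# uterseg

Semi-automated uterine segmentation and volumetry for paired T1-weighted
(T1W) and contrast-enhanced T1-weighted (enhanced-T1W) pelvic MRI.

Uterine fibroids are the most common benign tumors of the female pelvis,
and uterine artery embolization (UAE) treats them by shrinking the
uterus — so serial uterine volumetry on MRI is the follow-up measurement
that matters. Tracing the uterus by hand on every slice is slow and
poorly reproducible; `uterseg` implements a segmentation pipeline that
needs no training data or shape model, plus the evaluation metrics and
volume statistics used to validate it against manual tracing.

## Method

For each acquisition (sagittal, axial or coronal series) the pipeline
runs:

1. **Fuzzy C-means (FCM) clustering** of the enhanced-T1W intensities
   into *c* = 3 classes with fuzzifier *m* = 2, minimizing
   `J_m = Σ_i Σ_k u_ik^m ‖x_k − v_i‖²` under column-stochastic
   memberships `Σ_i u_ik = 1`. Gadolinium-perfused uterine tissue
   enhances strongly, so the candidate mask is the hard assignment of
   the class with the brightest prototype `v_i`.
2. **Morphological refinement**: hole filling (devascularized
   "infarcted" fibroids have low enhanced signal and punch holes in the
   cluster), opening (removes debris, severs weak bridges), and
   selection of the largest centrally located connected component
   (score `size / (1 + d_c)` with `d_c` the centroid-to-image-centre
   distance).
3. **T1W refinement**: colon that touches the uterine fundus can
   enhance like the uterus and survive step 2, but is distinctly
   brighter on plain T1W. The T1W volume is registered to the
   enhanced-T1W volume (12-DOF affine, correlation-ratio similarity,
   trilinear resampling), the candidate mask is projected onto it, and
   candidate voxels at or above the start of the masked histogram's
   last peak — the valley preceding it — are removed. A final
   size-dependent opening/closing pass cleans residual tethers.

Evaluation of an automated mask *A* against a manual mask *M* reports
the similarity index `S_i = 2N_TP/(N_M+N_A)·100`, Jaccard index
`J_i = N_TP/(N_M+N_A−N_TP)·100`, sensitivity `T_P = N_TP/N_M·100`,
specificity `S_E = 100 − N_FP/N_A·100`, and Hausdorff / mean surface
distance in mm (anisotropy-aware). Volumetry multiplies foreground
voxels by voxel volume and averages the three per-view estimates;
`compare_methods` reports Pearson *r*, the OLS fit of manual on
automated measurements, *R²*, and the mean percent difference.

Because no patient data ships with the package, a synthetic phantom
generator renders paired T1W/enhanced-T1W volumes with ground truth —
bright uterus, colon confounder with matching enhanced intensity,
dark fibroid holes, optional noise and a recorded affine
misregistration — so every stage is testable end to end.

## Worked example

```python
from uterseg import PipelineConfig, evaluate_masks, run_pipeline
from uterseg.phantom import generate, preset

t1, t1c, truth = generate(preset("default"))   # noise-free phantom
mask, prov = run_pipeline(t1c, t1, PipelineConfig(registration_enabled=False))
rep = evaluate_masks(truth, mask)
print(f"SI={rep.si:.2f}%  TP={rep.tp:.2f}%  SP={rep.sp_paper:.2f}%  "
      f"HD={rep.hd:.2f}mm  threshold={prov.threshold:.1f}")
```

prints

```
SI=99.89%  TP=99.78%  SP=100.00%  HD=1.00mm  threshold=84.8
```

i.e. the pipeline recovers 99.9% Dice overlap with the phantom's true
uterus; the histogram threshold of ≈85 falls between the uterus (80)
and colon (160) T1W means, which is what removes the colon appendage
from the final mask (specificity 100%). The same flow is available from
the shell:

```bash
uterseg phantom --preset default --out ph/
uterseg run --enhanced ph/t1c.nii.gz --t1 ph/t1.nii.gz \
            --manual ph/truth.nii.gz --pre-registered --out out/
uterseg evaluate --manual ph/truth.nii.gz --auto out/uterus_mask.nii.gz
```

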