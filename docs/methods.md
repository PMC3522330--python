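# Methods

This note documents the models, parameters, numerical choices and
limitations of `uterseg`. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

An `IntensityVolume` is a 3D scalar array with voxel spacing
`(dx, dy, dz)` in mm; clinical acquisitions of this kind are strongly
anisotropic (e.g. 0.78 mm in-plane, 7 mm slices), so all physical
distances are computed per-axis as index difference × spacing. 2D
slices are promoted to `(H, W, 1)`. Modality (T1W vs enhanced-T1W) and
view (sagittal/axial/coronal) are not recoverable from NIfTI headers
and are supplied by the caller. Loading rejects non-3D images and
non-finite voxels (opt-in sanitization replaces them with 0). Masks are
stored as uint8 {0,1} NIfTI and round-trip voxel-exactly.

## Fuzzy C-means

`FuzzyCMeans` implements the standard alternating optimization of
`J_m = Σ_i Σ_k u_ik^m d_ik²`, `d_ik = ‖x_k − v_i‖`:

- membership update `u_ik = 1 / Σ_j (d_ik/d_jk)^(2/(m−1))`; a sample
  coinciding with a centre gets crisp membership (the limit of the
  formula), with coincident centres tie-broken to the lowest index;
- centre update `v_i = Σ_k u_ik^m x_k / Σ_k u_ik^m`;
- stop when the largest centre shift drops below `tol` (default 1e-5)
  or after `max_iter` (default 300) iterations.

Both steps are exact coordinate minimizations, so the recorded
objective trace is non-increasing; the suite asserts this and checks
agreement with an independent loop-coded FCM to 1e-6 on small
instances.

Choices:

- **Initialization.** Centres start at the `(2i+1)/(2c)` intensity
  quantiles. This is deterministic without a seed and yields centres
  ordered by intensity, matching the interpretation of the brightest
  class as the enhancing tissue; a seeded random init is available.
- **Feature space** is scalar intensity only. `c = 3` and `m = 2` are
  the protocol defaults: background/dark tissue, intermediate soft
  tissue, and enhancing tissue.
- **Rescaling.** Intensities are min-max rescaled to [0, 1] before
  clustering so `tol` means the same thing across scanners; reported
  centres are mapped back to original units.
- Clustering is run on all voxels of the supplied array at once;
  intensity clustering is spatially agnostic, so 2D slices and 3D
  volumes share one code path.

`select_enhanced_class` hard-assigns each voxel to its
maximum-membership class and returns the class with the largest centre;
membership ties go to the brighter class. The output is invariant to
cluster relabeling.

## Morphology

- **Hole filling**: background components not connected to the border
  become foreground. In per-slice mode this runs per 2D slice so a
  cavity open only through a neighbouring slice still fills; a
  single-slice volume is always treated in-plane (a promoted 2D image
  has no 3D hole interior).
- **Opening/closing** use disk (in-plane), ball or cube structuring
  elements; arrays are zero-padded by the element radius first, so
  anti-extensivity, extensivity and idempotence hold exactly — except
  that a crack running to the border is genuinely open to the outside
  and its mouth voxels stay background under true closing.
- **Component selection**: components are 8-connected per slice,
  26-connected in 3D. "Largest and central" is scored as
  `size / (1 + d_c)` with `d_c` the centroid-to-centre distance in
  voxels — monotone in both criteria and parameter-free; pure-largest
  and pure-most-central modes are available. An empty input yields an
  empty output plus a warning flag rather than an error, so a slice
  without uterus does not abort a stack.
- Default opening radius: 1 voxel (no physical size is mandated by the
  protocol; 1 voxel removes speckle without eroding organ-scale
  structure at these resolutions).

## Registration and T1W refinement

**Transform.** 12-DOF affine `y = M x + t` on physical coordinates
(mm), parametrized as translation (mm), rotation (deg, about the fixed
image's physical centre), scale and shear (%), composed as
`R_z R_y R_x · Shear · Scale`.

**Resampling** is pull-back trilinear interpolation onto the fixed
grid with 0 outside the field of view; integer-voxel translations
reproduce exact shifted copies (cross-checked against SimpleITK's
resampler on interior voxels).

**Similarity** is the correlation ratio η²(fixed | moving): the
fraction of fixed-image intensity variance explained by the moving
image binned into 32 quantile bins. The moving image is the predictor
because the T1W image separates tissues (colon vs uterus) that the
enhanced image deliberately cannot — predicting in the other direction
is bounded away from 1 by exactly the ambiguity the pipeline exploits.
Quantile binning makes the metric exactly invariant under strictly
monotone remappings of the moving image. Two numerical safeguards keep
the metric's optimum at the true alignment:

- bin edges are frozen from the untransformed moving image, so the
  partition cannot refine itself on interpolation-blurred values (an
  adaptive partition rewards transforms that blur the predictor);
- both images are Gaussian-smoothed by 0.8 voxel for metric evaluation
  only, keeping the phase-dependent part of interpolation blur small
  against the edge width.

**Optimizer.** Multi-start (identity + seeded ±5 mm/±5° perturbations)
staged Powell search — translation, then rigid, then full affine — on
a coarse level decimated ×2 (in-plane, and through-slice for stacks of
≥16 slices), followed by a full-affine Powell polish at full
resolution. Deterministic given the seed. If the best transform does
not improve η² over identity by at least 0.02, identity is returned
with a warning: content-free or disjoint images can buy a spurious η²
of order 1e-2 from out-of-field zeros. Constant-intensity inputs short
circuit to identity immediately. Registration is optional
(`--pre-registered`) for data aligned upstream.

**Histogram threshold.** The masked T1W intensities are histogrammed
into 64 equal-width bins, smoothed by a centred 5-bin moving average,
and scanned for local maxima with prominence ≥ 5% of the highest
smoothed count (the smoothed array is padded with sentinels so modes in
the extreme bins are detectable). The removal threshold — "where the
last peak starts" — is the centre of the lowest bin between the last
two peaks. With at most one peak the distribution is taken as
single-tissue and the threshold is placed one bin width above the
maximum, so nothing is removed. Candidate voxels at or above the
threshold (colon is the brighter T1W tissue) are dropped; the operation
never adds voxels.

**Post-processing** applies opening then closing with radius
`max(1, round(α · size^(1/3)))` in 3D (square root in 2D), α = 0.05 by
default — the radius scales with the linear extent of the region,
which is all the "element size depends on the region size" contract
pins down — then re-selects the central component.

## Evaluation metrics

`N_TP = |M ∩ A|`, `N_FP = |A \ M|`. The Jaccard index uses the
standard union denominator `N_M + N_A − N_TP`, which satisfies the
Dice–Jaccard identity `S_i = 2J/(1+J)` (asserted to 1e-9); a variant
with denominator `N_M + N_A + N_TP` that appears in print for this
protocol is available behind `jaccard="printed"` for comparison — it
scores identical masks at 33%, which is why it is not the default.
"Specificity" here is `100 − N_FP/N_A·100`, i.e. a precision, not the
classical true-negative rate; it is exposed as `sp_paper` to avoid the
confusion. Surfaces are foreground voxels with a background
face-neighbour (the outside counts as background); voxel centres form
the point sets; distances are Euclidean in mm. The Hausdorff distance
takes the max of both directed max-min distances; the mean distance is
the symmetric mean of the two directed averages (both directed means
are also reported). Per-slice tables use within-plane distances.

## Volumetry

Volume is `N · dx · dy · dz`; per-slice area summation × thickness is
identical for axis-aligned grids (asserted). Multi-view estimates are
arithmetically averaged; missing views are excluded with a warning.
`compare_methods` computes Pearson r, the OLS fit of the manual on the
automated measurement, R², and mean |m−a|/m·100; these are
data-dependent descriptive outputs, not constants of the method.

## Phantom

Default grid 96×96×24 at (1, 1, 3) mm — small enough for seconds-scale
FCM/morphology tests, anisotropic like clinical data. Structures:

- uterus: ellipsoid, semi-axes (24, 18, 8) voxels;
- colon: tube along x touching the uterus on its low-y boundary, with
  enhanced-T1W mean exactly equal to the uterus (the strongest form of
  the intensity ambiguity) and T1W mean 160 vs 80 for the uterus, well
  beyond the 4σ separability margin the validator enforces;
- fibroid holes: two ellipsoids strictly inside the uterus, dark on
  both modalities. Ground truth is the whole uterus including fibroid
  voxels — the clinical target is the organ.

Additive Gaussian noise (independent draws per modality) rather than
Rician: the pipeline operates far from the low-SNR magnitude regime.
The "noisy" preset uses σ = 10, i.e. SNR ≈ 20 on the enhancing tissue.
The "trivial" preset (uterus only) carries a ±15 linear background
ramp standing in for smooth non-enhancing anatomy, keeping three
intensity classes well defined.

Rendering evaluates the analytic geometry at voxel centres (hard
edges) by default. The misregistered preset instead supersamples 3× per
axis (partial-volume edges) and renders the T1W geometry directly on
the transformed grid: sub-voxel transform recovery is only well posed
when the images sample a continuous scene, and resampling an aligned
render would displace the similarity optimum through interpolation
blur. The recorded transform (5-voxel in-plane translation + 3°
rotation) is recovered by `register_affine` within 0.5 voxel and 2%
scale; the acceptance script measures the actual errors.

What the phantom does *not* emulate: anatomically realistic pelvic
anatomy, intensity inhomogeneity (bias fields), Rician noise, motion,
or partial-volume mixing with more than one neighbouring tissue.
Passing tests therefore demonstrate the pipeline's mechanics —
clustering, hole filling, confounder removal, metric correctness,
transform recovery — not clinical-grade accuracy on patient data,
which published results for this class of method put at roughly 80%
Dice against manual tracing.

## Pipeline and provenance

Stages run in the order clustering → class selection → hole filling →
opening → central component → [registration → resampling] → masked
histogram → threshold refinement → post-processing. Per-view series
are segmented independently and volumetry averages the per-view
volumes. Every run returns a `ProvenanceRecord` (config snapshot,
per-stage voxel counts and warnings, threshold, transform, version)
that round-trips through JSON; re-running from a record's config with
the same inputs reproduces the mask bit-for-bit. An intermediate stage
that empties the mask aborts with the stage name and the provenance
collected so far.

## Problem sizes used in the checked experiments

The test suite and acceptance script run the full pipeline on the
96×96×24 phantom (221k voxels), registration recovery on the same grid
(with a half-scale 48×48×12 fixture for the unit tests), brute-force
metric oracles on 200 random 16×16×4 mask pairs, and FCM reference
checks on ≤20-sample instances — sizes chosen so each oracle is
exhaustively computable while the geometry still exhibits every
structure the method must handle.

## Known limitations

- The FCM stage assumes the enhancing class is the brightest; strongly
  enhancing non-uterine structures other than the modelled colon
  (vessels, bladder wall) are only removed if the T1W contrast or the
  central-component selection catches them.
- The last-peak threshold needs the colon mode to be resolvable in the
  64-bin histogram; a colon fragment far smaller than the prominence
  floor (5% of the main mode) would survive.
- Registration is single-channel affine; deformable motion between the
  T1W and enhanced acquisitions is out of scope.
- The η²-improvement floor of 0.02 means marginal but genuine
  registrations are conservatively replaced by identity.
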