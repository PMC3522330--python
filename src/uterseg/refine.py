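"""Colon removal via the registered T1W image and histogram thresholding.

On enhanced-T1W the colon can enhance like the uterus and, where it
touches the uterine fundus, survives the morphological cleanup inside
the candidate mask.  On plain T1W the colon is distinctly brighter, so
the candidate is projected onto the T1W image (after 12-DOF affine
registration with a correlation-ratio similarity and trilinear
resampling), the masked T1W intensities are histogrammed, and voxels at
or above the start of the histogram's last peak — operationalised as
the last valley before that peak — are removed.  A size-dependent
opening-then-closing pass then clears any residual tethers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .core import BinaryMask, IntensityVolume, PipelineConfig
from .morphology import SEShape, StructuringElement, closing, largest_central_component, opening

__all__ = [
    "AffineTransform",
    "HistogramModel",
    "correlation_ratio",
    "register_affine",
    "resample",
    "mask_intensities",
    "last_peak_threshold",
    "threshold_refine",
    "postprocess",
]


@dataclass(frozen=True)
class AffineTransform:
    """Affine map from fixed-image physical coords (mm) to moving-image
    physical coords: ``y = matrix @ x + translation``.

    Physical coordinates are voxel index times spacing, per axis.
    """

    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,) mm
    similarity_value: float = float("nan")

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(M)) <= 1e-9:
            raise ValueError("affine matrix is (near-)singular")
        object.__setattr__(self, "matrix", M)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, similarity_value: float = float("nan")) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), similarity_value)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_mm)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        Minv = np.linalg.inv(self.matrix)
        return AffineTransform(Minv, -Minv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first."""
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )


def resample(
    volume: IntensityVolume,
    transform: AffineTransform,
    reference: IntensityVolume | None = None,
) -> IntensityVolume:
    """Pull-back resampling onto the reference grid, trilinear, 0 outside.

    Output voxel at index ``i`` reads the moving volume at physical
    position ``transform(i * ref_spacing)``; integer-voxel translations
    therefore reproduce exact shifted copies.
    """
    ref = reference if reference is not None else volume
    sp_fix = np.asarray(ref.spacing)
    sp_mov = np.asarray(volume.spacing)
    A = (transform.matrix * sp_fix[None, :]) / sp_mov[:, None]
    offset = transform.translation / sp_mov
    out = ndimage.affine_transform(
        volume.data,
        matrix=A,
        offset=offset,
        output_shape=ref.shape,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return IntensityVolume(
        data=out, spacing=ref.spacing, modality=volume.modality, view=volume.view
    )


def quantile_bin_edges(values: np.ndarray, bins: int = 32) -> np.ndarray:
    """Interior quantile edges partitioning ``values`` into ``bins`` groups."""
    v = np.asarray(values, dtype=float).reshape(-1)
    return np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])


def correlation_ratio(
    predictor: np.ndarray,
    response: np.ndarray,
    bins: int = 32,
    edges: np.ndarray | None = None,
) -> float:
    """η²(response | predictor): fraction of response variance explained
    by the quantile-binned predictor.

    Quantile binning makes the value exactly invariant under any
    strictly monotone remapping of the predictor image, the property
    that lets the metric register images with non-linear (but monotone)
    intensity relationships.  ``edges`` substitutes precomputed interior
    bin edges (the registration driver freezes them from the
    untransformed moving image so bin granularity cannot adapt to — and
    thereby reward — interpolation blur).
    """
    x = np.asarray(predictor, dtype=float).reshape(-1)
    y = np.asarray(response, dtype=float).reshape(-1)
    var = y.var()
    if var == 0.0 or x.size < 2:
        return 0.0
    if edges is None:
        edges = quantile_bin_edges(x, bins)
    bins = len(edges) + 1
    groups = np.searchsorted(edges, x, side="right")
    n_k = np.bincount(groups, minlength=bins)
    nz = n_k > 0
    sums = np.bincount(groups, weights=y, minlength=bins)[nz]
    sq = np.bincount(groups, weights=y * y, minlength=bins)[nz]
    within = sq - sums**2 / n_k[nz]
    eta2 = 1.0 - within.sum() / (y.size * var)
    return float(np.clip(eta2, 0.0, 1.0))


# --- 12-parameter vector <-> transform ------------------------------------
# p = [tx,ty,tz (mm), rx,ry,rz (deg), sx,sy,sz (%), kxy,kxz,kyz (%)]


def params_to_transform(p: np.ndarray, center_mm: np.ndarray) -> AffineTransform:
    t = np.asarray(p[0:3], dtype=float)
    rx, ry, rz = np.deg2rad(p[3:6])
    scale = 1.0 + np.asarray(p[6:9], dtype=float) / 100.0
    kxy, kxz, kyz = np.asarray(p[9:12], dtype=float) / 100.0
    cx, sx_ = np.cos(rx), np.sin(rx)
    cy, sy_ = np.cos(ry), np.sin(ry)
    cz, sz_ = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    Ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    Rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    K = np.array([[1, kxy, kxz], [0, 1, kyz], [0, 0, 1]])
    M = Rz @ Ry @ Rx @ K @ np.diag(scale)
    translation = center_mm - M @ center_mm + t
    return AffineTransform(M, translation)


def _grid_center_mm(volume: IntensityVolume) -> np.ndarray:
    return (np.asarray(volume.shape) - 1) / 2.0 * np.asarray(volume.spacing)


def _downsample(volume: IntensityVolume) -> IntensityVolume:
    """Coarse level: decimate in-plane by 2 (and through-slice when the
    stack is deep enough); clinical slices are already thick."""
    step_z = 2 if volume.shape[2] >= 16 else 1
    data = volume.data[::2, ::2, ::step_z]
    dx, dy, dz = volume.spacing
    return IntensityVolume(
        data=data,
        spacing=(dx * 2, dy * 2, dz * step_z),
        modality=volume.modality,
        view=volume.view,
    )


def register_affine(
    moving: IntensityVolume, fixed: IntensityVolume, config: PipelineConfig
) -> AffineTransform:
    """12-DOF affine registration maximizing the correlation ratio.

    Multi-start derivative-free (Powell) search, seeded from identity
    plus ``registration_multistart - 1`` seeded random perturbations, on
    a 2-level pyramid (decimated, then full resolution).  Deterministic
    given ``config.rng_seed``.  If the optimum does not improve on the
    identity transform, identity is returned with a warning.
    """
    bins = config.registration_bins
    center = _grid_center_mm(fixed)
    if moving.data.var() == 0.0 or fixed.data.var() == 0.0:
        warnings.warn(
            "content-free image (constant intensity); returning identity",
            stacklevel=2,
        )
        return AffineTransform.identity(similarity_value=0.0)

    def smoothed(vol: IntensityVolume) -> IntensityVolume:
        # symmetric ~0.8-voxel Gaussian: regularizes the staircase cost
        # landscape of sharp-edged images and keeps the phase-dependent
        # part of the interpolation blur small against the edge width,
        # so the similarity optimum stays at the true alignment
        return vol.with_data(ndimage.gaussian_filter(vol.data, sigma=0.8))

    fixed_s, moving_s = smoothed(fixed), smoothed(moving)
    coarse_fix = _downsample(fixed_s)
    coarse_mov = _downsample(moving_s)

    def cost_on(fix, mov):
        # bin edges frozen from the untransformed moving image: constant
        # partition across candidate transforms (and exactly monotone-
        # remap invariant, since a remap moves the edges with the data)
        frozen_edges = quantile_bin_edges(mov.data, bins)

        def cost(p):
            tr = params_to_transform(p, center)
            res = resample(mov, tr, reference=fix)
            return -correlation_ratio(res.data, fix.data, edges=frozen_edges)

        return cost

    rng = np.random.default_rng(config.rng_seed)
    starts = [np.zeros(12)]
    for _ in range(max(0, config.registration_multistart - 1)):
        p = np.zeros(12)
        p[0:3] = rng.uniform(-5.0, 5.0, 3)  # mm
        p[3:6] = rng.uniform(-5.0, 5.0, 3)  # deg
        starts.append(p)

    def powell_subset(cost, p0, active, xtol, maxfev):
        """Powell over the ``active`` parameter block, others frozen."""
        p0 = np.asarray(p0, dtype=float)

        def sub(q):
            p = p0.copy()
            p[active] = q
            return cost(p)

        res = optimize.minimize(
            sub,
            p0[active],
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-9, "maxfev": maxfev},
        )
        p = p0.copy()
        p[active] = res.x
        return p, float(res.fun)

    # staged search: translation -> rigid -> full affine (coarse level),
    # then a full-affine polish at full resolution
    trans = np.arange(3)
    rigid = np.arange(6)
    full = np.arange(12)
    coarse_cost = cost_on(coarse_fix, coarse_mov)
    best_p, best_f = None, np.inf
    for p0 in starts:
        p, _ = powell_subset(coarse_cost, p0, trans, 1e-2, 600)
        p, _ = powell_subset(coarse_cost, p, rigid, 1e-2, 1500)
        p, f = powell_subset(coarse_cost, p, full, 1e-3, 3000)
        if f < best_f:
            best_p, best_f = p, f

    fine_cost = cost_on(fixed_s, moving_s)
    x, fun = powell_subset(fine_cost, best_p, full, 1e-4, 4000)
    res = optimize.OptimizeResult(x=x, fun=fun)
    identity_sim = -fine_cost(np.zeros(12))
    final_sim = -res.fun
    # require a real improvement: out-of-field zeros can buy a spurious
    # eta^2 of O(1e-2) on content-free images
    if final_sim <= identity_sim + 0.02:
        warnings.warn(
            "registration did not improve on identity; returning identity",
            stacklevel=2,
        )
        return AffineTransform.identity(similarity_value=identity_sim)
    tr = params_to_transform(res.x, center)
    return AffineTransform(tr.matrix, tr.translation, similarity_value=final_sim)


# --- histogram thresholding ------------------------------------------------


@dataclass(frozen=True)
class HistogramModel:
    """Smoothed masked-intensity histogram with detected peaks and the
    removal threshold at the start (preceding valley) of the last peak."""

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed_counts: np.ndarray
    peaks: np.ndarray  # indices into counts
    threshold: float
    single_peak_fallback: bool = False


def mask_intensities(t1_registered: IntensityVolume, candidate: BinaryMask) -> np.ndarray:
    """Intensities of the registered T1W image inside the candidate mask."""
    if t1_registered.shape != candidate.shape:
        raise ValueError("volume and mask grids differ")
    if candidate.voxel_count == 0:
        warnings.warn("mask_intensities: empty candidate mask", stacklevel=2)
        return np.empty(0, dtype=float)
    return t1_registered.data[candidate.data]


def last_peak_threshold(values: np.ndarray, config: PipelineConfig) -> HistogramModel:
    """Threshold at the start of the last histogram peak.

    The histogram (``histogram_bins`` equal-width bins, smoothed by a
    centred moving average of ``histogram_smoothing`` bins) is scanned
    for local maxima with prominence at least ``peak_prominence`` of the
    highest smoothed count.  With two or more peaks the threshold is the
    centre of the lowest bin between the last two peaks — the valley
    where the last (brightest) peak starts.  With at most one peak the
    distribution is taken as single-tissue and the threshold is placed
    one bin width above the maximum so nothing is removed.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    if values.size == 0:
        raise ValueError("cannot build a histogram from an empty value list")
    vrange = float(np.ptp(values))
    if vrange == 0.0:
        eps = max(abs(values[0]) * 1e-6, 1e-6)
        return HistogramModel(
            bin_edges=np.array([values[0], values[0]]),
            counts=np.array([values.size]),
            smoothed_counts=np.array([float(values.size)]),
            peaks=np.array([0]),
            threshold=float(values[0] + eps),
            single_peak_fallback=True,
        )
    counts, edges = np.histogram(values, bins=config.histogram_bins)
    w = config.histogram_smoothing
    w += 1 - w % 2  # force odd width so the window is centred
    kernel = np.ones(w) / w
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    # pad with sentinels so modes in the first/last bin are detectable
    padded = np.concatenate([[-1.0], smoothed, [-1.0]])
    peaks, _ = signal.find_peaks(
        padded, prominence=config.peak_prominence * smoothed.max()
    )
    peaks = peaks - 1
    bin_width = edges[1] - edges[0]
    if len(peaks) <= 1:
        return HistogramModel(
            bin_edges=edges,
            counts=counts,
            smoothed_counts=smoothed,
            peaks=peaks,
            threshold=float(values.max() + bin_width),
            single_peak_fallback=True,
        )
    prev_peak, last_peak = peaks[-2], peaks[-1]
    valley = prev_peak + int(np.argmin(smoothed[prev_peak : last_peak + 1]))
    threshold = float((edges[valley] + edges[valley + 1]) / 2.0)
    return HistogramModel(
        bin_edges=edges,
        counts=counts,
        smoothed_counts=smoothed,
        peaks=peaks,
        threshold=threshold,
        single_peak_fallback=False,
    )


def threshold_refine(
    candidate: BinaryMask, t1_registered: IntensityVolume, hist: HistogramModel
) -> BinaryMask:
    """Drop candidate voxels at or above the threshold (colon is the
    brighter T1W tissue); never adds voxels."""
    if t1_registered.shape != candidate.shape:
        raise ValueError("volume and mask grids differ")
    out = candidate.data & (t1_registered.data < hist.threshold)
    if candidate.voxel_count > 0 and not out.any():
        warnings.warn("threshold_refine removed every candidate voxel", stacklevel=2)
    return candidate.with_data(out)


def postprocess(
    mask: BinaryMask,
    config: PipelineConfig,
    region_size: int | None = None,
) -> BinaryMask:
    """Opening then closing with a size-dependent structuring element,
    then re-selection of the central component.

    The radius scales with the linear extent of the region:
    ``r = max(1, round(alpha * size**(1/3)))`` in 3D (square root for a
    single slice), with ``alpha = config.postprocess_alpha``.
    """
    size = mask.voxel_count if region_size is None else int(region_size)
    if size == 0:
        return mask.with_data(np.zeros_like(mask.data))
    is_3d = mask.shape[2] > 1
    extent = size ** (1.0 / 3.0) if is_3d else size**0.5
    r = max(1, int(round(config.postprocess_alpha * extent)))
    se = StructuringElement(SEShape.BALL if is_3d else SEShape.DISK, radius=r)
    out = closing(opening(mask, se), se)
    mode = "per-slice" if config.component_mode == "per-slice" else "volume"
    out, _ = largest_central_component(out, mode=mode, score=config.component_score)
    return out
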