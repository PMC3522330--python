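"""Shared data types, NIfTI I/O and grid bookkeeping.

Everything downstream operates on two containers: :class:`IntensityVolume`
(a 3D scalar MR image with voxel spacing in mm) and :class:`BinaryMask`
(a boolean region on the same grid).  Voxel indices are 0-based and all
physical distances are index differences scaled per-axis by the spacing,
so anisotropic acquisitions (e.g. 0.78 mm in-plane, 7 mm slices) are
honoured throughout.  2D inputs are promoted to shape ``(H, W, 1)``.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "View",
    "IntensityVolume",
    "BinaryMask",
    "PipelineConfig",
    "FormatError",
    "DegenerateInputError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class FormatError(ValueError):
    """Input file or array violates the expected image format."""


class DegenerateInputError(ValueError):
    """Input is valid but too degenerate for the requested operation."""


class Modality(str, enum.Enum):
    T1W = "T1W"
    T1W_ENHANCED = "T1W_ENHANCED"
    UNKNOWN = "UNKNOWN"


class View(str, enum.Enum):
    SAGITTAL = "SAGITTAL"
    AXIAL = "AXIAL"
    CORONAL = "CORONAL"
    UNKNOWN = "UNKNOWN"


def _as_3d(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data)
    # squeeze trailing singleton dimensions (common in NIfTI exports)
    while arr.ndim > 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim == 2:
        arr = arr[:, :, np.newaxis]
    if arr.ndim != 3:
        raise FormatError(f"expected a 2D or 3D image, got {arr.ndim} dimensions")
    return arr


def _check_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise FormatError(f"spacing must have 3 components, got {len(sp)}")
    if not all(np.isfinite(sp)) or any(s <= 0 for s in sp):
        raise FormatError(f"spacing components must be finite and > 0, got {sp}")
    return sp


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar image with voxel spacing (mm) and acquisition tags."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = Modality.UNKNOWN
    view: View = View.UNKNOWN

    def __post_init__(self):
        arr = _as_3d(self.data).astype(np.float64, copy=False)
        if not np.all(np.isfinite(arr)):
            raise FormatError("volume contains NaN/Inf voxels")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def with_data(self, data: np.ndarray) -> "IntensityVolume":
        return dataclasses.replace(self, data=data)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean region on a voxel grid; carries the grid spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        arr = _as_3d(self.data)
        if arr.dtype != bool:
            arr = arr > 0
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(data=data, spacing=self.spacing)

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=1e-5
        )


@dataclass
class PipelineConfig:
    """All tunable parameters of the segmentation pipeline.

    Defaults follow the study protocol where one is stated (``c = 3``
    clusters, fuzzifier ``m = 2``) and documented package choices
    elsewhere.
    """

    c: int = 3
    m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    fcm_init: str = "quantile"  # "quantile" | "random"
    rng_seed: int = 0
    opening_radius: int = 1
    component_mode: str = "volume"  # "volume" | "per-slice"
    component_score: str = "combined"  # "combined" | "largest" | "central"
    histogram_bins: int = 64
    histogram_smoothing: int = 5
    peak_prominence: float = 0.05
    registration_enabled: bool = True
    registration_bins: int = 32
    registration_multistart: int = 3
    postprocess_alpha: float = 0.05

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.c < 2:
            raise ValueError(f"cluster count c must be >= 2, got {self.c}")
        if self.m <= 1:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if self.fcm_tol <= 0:
            raise ValueError("fcm_tol must be > 0")
        if self.fcm_max_iter < 1:
            raise ValueError("fcm_max_iter must be >= 1")
        if self.opening_radius < 1:
            raise ValueError("opening_radius must be >= 1")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.histogram_smoothing < 1:
            raise ValueError("histogram_smoothing must be >= 1")
        if self.component_mode not in ("volume", "per-slice"):
            raise ValueError(f"unknown component_mode {self.component_mode!r}")
        if self.component_score not in ("combined", "largest", "central"):
            raise ValueError(f"unknown component_score {self.component_score!r}")
        if self.fcm_init not in ("quantile", "random"):
            raise ValueError(f"unknown fcm_init {self.fcm_init!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


# ---------------------------------------------------------------------------
# NIfTI I/O


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    if len(zooms) == 2:
        zooms = (*zooms, 1.0)
    return _check_spacing(zooms)


def read_volume(
    path,
    modality: Modality | str = Modality.UNKNOWN,
    view: View | str = View.UNKNOWN,
    sanitize_nan: bool = False,
) -> IntensityVolume:
    """Load a NIfTI volume; spacing comes from the header ``pixdim``.

    Modality and view are not stored in NIfTI, so they are supplied by
    the caller (CLI flags / sidecar config).  Non-finite voxels are
    rejected unless ``sanitize_nan`` replaces them with 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = _as_3d(data).astype(np.float64)
    if not np.all(np.isfinite(data)):
        if sanitize_nan:
            data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
        else:
            raise FormatError(f"{path} contains non-finite voxels")
    return IntensityVolume(
        data=data,
        spacing=_spacing_from_header(img),
        modality=Modality(modality),
        view=View(view),
    )


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def write_volume(volume: IntensityVolume, path) -> None:
    img = nib.Nifti1Image(
        volume.data.astype(np.float32), _affine_from_spacing(volume.spacing)
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as uint8 {0,1} NIfTI; round-trips voxel-for-voxel."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine_from_spacing(mask.spacing)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = _as_3d(np.asanyarray(img.dataobj))
    return BinaryMask(data=data > 0, spacing=_spacing_from_header(img))
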