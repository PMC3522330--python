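"""Mask-based volumetry and manual-vs-automated method comparison.

Uterine volume is the foreground voxel count times the voxel volume.
When the segmentation is run independently on sagittal, axial and
coronal series, the final estimate is the arithmetic mean of the three
per-view volumes.  Method agreement over a set of paired section areas
(or volumes) is summarised by the Pearson correlation, the ordinary
least-squares regression of the manual measurement on the automated
one, R², and the mean percent area difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BinaryMask, View

__all__ = [
    "VolumeEstimate",
    "MethodComparison",
    "mask_volume",
    "slice_areas",
    "average_views",
    "compare_methods",
]


@dataclass(frozen=True)
class VolumeEstimate:
    per_view: dict
    mean_volume: float  # mm^3
    per_slice_areas: dict = field(default_factory=dict)  # view -> list of mm^2


@dataclass(frozen=True)
class MethodComparison:
    pearson_r: float
    regression_slope: float
    regression_intercept: float
    r_squared: float
    mean_pct_area_diff: float
    n_pairs: int
    flags: tuple = ()


def mask_volume(mask: BinaryMask) -> float:
    """Volume in mm³: N_true × dx × dy × dz."""
    return mask.voxel_count * mask.voxel_volume_mm3


def slice_areas(mask: BinaryMask) -> np.ndarray:
    """Per-slice foreground area in mm² along the through-slice axis."""
    dx, dy, _ = mask.spacing
    return mask.data.sum(axis=(0, 1)) * dx * dy


def average_views(per_view: dict) -> VolumeEstimate:
    """Arithmetic mean of the available per-view volumes (mm³).

    Views may be passed as :class:`View` or strings; ``None`` entries
    (missing acquisitions) are excluded with a warning.
    """
    if not per_view:
        raise ValueError("no per-view volumes supplied")
    present = {str(getattr(k, "value", k)): v for k, v in per_view.items() if v is not None}
    if not present:
        raise ValueError("all per-view volumes are missing")
    if len(present) < len(per_view):
        warnings.warn(
            f"averaging {len(present)} of {len(per_view)} views (missing views excluded)",
            stacklevel=2,
        )
    vols = np.asarray(list(present.values()), dtype=float)
    if np.any(vols < 0):
        raise ValueError("volumes must be non-negative")
    return VolumeEstimate(per_view=present, mean_volume=float(vols.mean()))


def compare_methods(manual, automated) -> MethodComparison:
    """Agreement statistics between paired manual and automated measures.

    Fits manual = slope × automated + intercept by ordinary least
    squares and reports Pearson r, R² and the mean of |m − a| / m · 100.
    """
    m = np.asarray(manual, dtype=float)
    a = np.asarray(automated, dtype=float)
    if m.shape != a.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {a.shape}")
    if m.size < 3:
        raise ValueError("need at least 3 paired measurements")
    flags = []
    if np.ptp(m) == 0 or np.ptp(a) == 0:
        flags.append("zero variance in one method: correlation undefined")
        r = slope = intercept = r2 = float("nan")
    else:
        res = stats.linregress(a, m)
        r, slope, intercept = float(res.rvalue), float(res.slope), float(res.intercept)
        r2 = r * r
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.abs(m - a) / m * 100.0
    pct = pct[np.isfinite(pct)]
    if pct.size < m.size:
        flags.append("zero manual measurements excluded from percent difference")
    mean_pct = float(pct.mean()) if pct.size else float("nan")
    return MethodComparison(
        pearson_r=r,
        regression_slope=slope,
        regression_intercept=intercept,
        r_squared=r2,
        mean_pct_area_diff=mean_pct,
        n_pairs=int(m.size),
        flags=tuple(flags),
    )
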