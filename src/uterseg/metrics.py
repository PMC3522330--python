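"""Overlap and surface-distance evaluation of a (manual, automated) mask pair.

Six measures compare the manual reference M against the automated
segmentation A:

* similarity index  S_i = 2·N_TP / (N_M + N_A) · 100   (Dice)
* Jaccard index     J_i = N_TP / (N_M + N_A − N_TP) · 100
* sensitivity       T_P = N_TP / N_M · 100              (ratio of correct detection)
* ``sp_paper``      S_E = 100 − F_P,  F_P = N_FP / N_A · 100
* Hausdorff distance D_H = max(h(M,A), h(A,M)) in mm
* mean surface distance MD in mm (symmetric mean of the directed means)

``sp_paper`` is deliberately not the classical true-negative-rate
specificity: it is 100 minus the false-positive fraction of A (i.e. a
precision), which is how this evaluation protocol defines it.  An
alternative Jaccard denominator N_M + N_A + N_TP circulates in print
for this protocol; it is inconsistent with Dice (M = A would score 33%)
and is only available behind ``jaccard="printed"`` for comparison.

Distances honour anisotropic voxel spacing: surfaces are foreground
voxels with at least one background face-neighbour, voxel centres are
the point sets, and all distances are Euclidean in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BinaryMask

__all__ = [
    "MetricsReport",
    "overlap_metrics",
    "surface_distances",
    "evaluate_masks",
    "metrics_per_slice",
]

_FACE_STRUCT_3D = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class MetricsReport:
    """Evaluation measures for one (manual, automated) mask pair.

    Percentages are on a 0–100 scale; distances in mm.  Undefined
    ratios (empty M or A) are NaN with an explanatory flag.
    """

    si: float
    ji: float
    tp: float
    sp_paper: float
    hd: float = float("nan")
    md: float = float("nan")
    md_manual_to_auto: float = float("nan")
    md_auto_to_manual: float = float("nan")
    n_m: int = 0
    n_a: int = 0
    n_tp: int = 0
    n_fp: int = 0
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "si": self.si,
            "ji": self.ji,
            "tp": self.tp,
            "sp_paper": self.sp_paper,
            "hd_mm": self.hd,
            "md_mm": self.md,
            "md_manual_to_auto_mm": self.md_manual_to_auto,
            "md_auto_to_manual_mm": self.md_auto_to_manual,
            "n_m": self.n_m,
            "n_a": self.n_a,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
            "flags": list(self.flags),
        }


def _check_grids(M: BinaryMask, A: BinaryMask) -> None:
    if not M.same_grid(A):
        raise ValueError(
            f"masks are on different grids: {M.shape}@{M.spacing} vs {A.shape}@{A.spacing}"
        )


def overlap_metrics(M: BinaryMask, A: BinaryMask, jaccard: str = "standard") -> MetricsReport:
    """Voxel-overlap measures between manual mask M and automated mask A."""
    _check_grids(M, A)
    if jaccard not in ("standard", "printed"):
        raise ValueError(f"unknown jaccard variant {jaccard!r}")
    n_m = M.voxel_count
    n_a = A.voxel_count
    n_tp = int(np.count_nonzero(M.data & A.data))
    n_fp = n_a - n_tp
    flags: list[str] = []

    si = 200.0 * n_tp / (n_m + n_a) if n_m + n_a > 0 else float("nan")
    if n_m + n_a == 0:
        flags.append("both masks empty: si/ji undefined")
    denom = (n_m + n_a - n_tp) if jaccard == "standard" else (n_m + n_a + n_tp)
    ji = 100.0 * n_tp / denom if denom > 0 else float("nan")
    if n_m > 0:
        tp = 100.0 * n_tp / n_m
    else:
        tp = float("nan")
        flags.append("empty manual mask: sensitivity undefined")
    if n_a > 0:
        sp = 100.0 - 100.0 * n_fp / n_a
    else:
        sp = float("nan")
        flags.append("empty automated mask: specificity undefined")
    return MetricsReport(
        si=si, ji=ji, tp=tp, sp_paper=sp, n_m=n_m, n_a=n_a, n_tp=n_tp, n_fp=n_fp, flags=flags
    )


def _surface_points_mm(mask: BinaryMask) -> np.ndarray:
    """Centres (mm) of foreground voxels with a background face-neighbour.

    Voxels on the array border count as surface (outside is background).
    """
    interior = ndimage.binary_erosion(
        mask.data, structure=_FACE_STRUCT_3D, border_value=0
    )
    surf = mask.data & ~interior
    return np.argwhere(surf) * np.asarray(mask.spacing)[None, :]


def surface_distances(M: BinaryMask, A: BinaryMask) -> tuple[float, float]:
    """(Hausdorff, mean) surface distance in mm between M and A.

    ``h(M,A) = max_m min_a d(m,a)`` over surface points; the Hausdorff
    distance is the max of both directions, the mean distance the
    symmetric mean of both directed average distances.
    """
    _check_grids(M, A)
    if M.voxel_count == 0 or A.voxel_count == 0:
        raise ValueError("surface distances are undefined for empty masks")
    pm = _surface_points_mm(M)
    pa = _surface_points_mm(A)
    d_m_to_a = cKDTree(pa).query(pm)[0]
    d_a_to_m = cKDTree(pm).query(pa)[0]
    hd = float(max(d_m_to_a.max(), d_a_to_m.max()))
    md = float((d_m_to_a.mean() + d_a_to_m.mean()) / 2.0)
    return hd, md


def evaluate_masks(M: BinaryMask, A: BinaryMask, jaccard: str = "standard") -> MetricsReport:
    """Full report: overlap measures plus surface distances (when defined)."""
    rep = overlap_metrics(M, A, jaccard=jaccard)
    if rep.n_m > 0 and rep.n_a > 0:
        pm = _surface_points_mm(M)
        pa = _surface_points_mm(A)
        d_m_to_a = cKDTree(pa).query(pm)[0]
        d_a_to_m = cKDTree(pm).query(pa)[0]
        rep.hd = float(max(d_m_to_a.max(), d_a_to_m.max()))
        rep.md_manual_to_auto = float(d_m_to_a.mean())
        rep.md_auto_to_manual = float(d_a_to_m.mean())
        rep.md = (rep.md_manual_to_auto + rep.md_auto_to_manual) / 2.0
    else:
        rep.flags.append("surface distances undefined for empty mask")
    return rep


def metrics_per_slice(M: BinaryMask, A: BinaryMask, jaccard: str = "standard") -> pd.DataFrame:
    """Per-slice metric table along the through-slice axis.

    Distances are computed per 2D slice (within-plane), matching
    slice-profile plots of segmentation quality along the stack.
    """
    _check_grids(M, A)
    rows = []
    for k in range(M.shape[2]):
        Mk = BinaryMask(M.data[:, :, k : k + 1], M.spacing)
        Ak = BinaryMask(A.data[:, :, k : k + 1], A.spacing)
        rep = evaluate_masks(Mk, Ak, jaccard=jaccard)
        row = rep.to_dict()
        row.pop("flags")
        row["slice"] = k
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("slice")
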