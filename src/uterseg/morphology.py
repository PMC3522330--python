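"""Binary morphological refinement of the FCM candidate mask.

Three cleanup stages follow the initial clustering: hole filling (dark
infarcted fibroids inside the uterus cluster as a lower class and leave
holes), opening (removes small debris and severs thin bridges), and
selection of the largest centrally-located connected component as the
uterus candidate.

All operations are zero-padded before filtering so the usual algebraic
laws (anti-extensivity of opening, extensivity of closing, idempotence)
hold up to the array border.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, disk

from .core import BinaryMask

__all__ = [
    "SEShape",
    "StructuringElement",
    "fill_holes",
    "opening",
    "closing",
    "largest_central_component",
]


class SEShape(str, enum.Enum):
    DISK = "DISK"  # 2D disk, applied in-plane (no through-slice extent)
    BALL = "BALL"  # 3D ball
    SQUARE = "SQUARE"  # full (2r+1)^d block


@dataclass(frozen=True)
class StructuringElement:
    shape: SEShape = SEShape.DISK
    radius: int = 1

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")

    def footprint(self) -> np.ndarray:
        """3D footprint; DISK has unit extent along the slice axis."""
        r = self.radius
        if self.shape is SEShape.DISK:
            return disk(r)[:, :, np.newaxis].astype(bool)
        if self.shape is SEShape.BALL:
            return ball(r).astype(bool)
        return np.ones((2 * r + 1,) * 3, dtype=bool)


def _padded(op, data: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    pad = [(s // 2,) * 2 for s in footprint.shape]
    out = op(np.pad(data, pad), structure=footprint)
    sl = tuple(slice(p, d + p) for (p, _), d in zip(pad, data.shape))
    return out[sl]


def fill_holes(mask: BinaryMask, mode: str = "volume") -> BinaryMask:
    """Fill background components not connected to the border.

    ``mode="per-slice"`` fills each 2D slice independently, so a cavity
    open only through neighbouring slices still gets filled; ``"volume"``
    uses the full 3D connectivity.  Extensive and idempotent.
    """
    if mask.shape[2] == 1:
        mode = "per-slice"  # a promoted 2D slice has no 3D hole interior
    if mode == "per-slice":
        out = np.stack(
            [ndimage.binary_fill_holes(mask.data[:, :, k]) for k in range(mask.shape[2])],
            axis=2,
        )
    elif mode == "volume":
        out = ndimage.binary_fill_holes(mask.data)
    else:
        raise ValueError(f"unknown fill mode {mode!r}")
    return mask.with_data(out)


def opening(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Erosion then dilation; anti-extensive (output is a subset) and idempotent."""
    return mask.with_data(_padded(ndimage.binary_opening, mask.data, se.footprint()))


def closing(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Dilation then erosion; extensive (output is a superset) and idempotent."""
    return mask.with_data(_padded(ndimage.binary_closing, mask.data, se.footprint()))


def _keep_best_component(
    labels: np.ndarray, n: int, center: np.ndarray, score: str
) -> np.ndarray:
    """Pick one labelled component by size, centrality or the combined
    score size / (1 + d_c) with d_c the centroid-to-centre distance in
    voxels."""
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    centroids = np.asarray(ndimage.center_of_mass(np.ones_like(labels), labels, idx))
    d_c = np.linalg.norm(centroids - center[None, :], axis=1)
    if score == "largest":
        s = sizes
    elif score == "central":
        s = -d_c
    else:
        s = sizes / (1.0 + d_c)
    best = idx[int(np.argmax(s))]
    return labels == best


def largest_central_component(
    mask: BinaryMask, mode: str = "volume", score: str = "combined"
) -> tuple[BinaryMask, bool]:
    """Keep the top-scoring connected component (per slice or per volume).

    Components are 8-connected within a slice and 26-connected in 3D.
    The default score ``size / (1 + d_c)`` is monotone in both size and
    centrality; ``score="largest"`` / ``"central"`` select on one
    criterion only.  Returns the mask and a flag that is True when the
    input had no foreground (the output is then empty and a warning is
    emitted).
    """
    if score not in ("combined", "largest", "central"):
        raise ValueError(f"unknown score {score!r}")
    data = mask.data
    if not data.any():
        warnings.warn("largest_central_component: empty input mask", stacklevel=2)
        return mask.with_data(np.zeros_like(data)), True

    if mode == "per-slice":
        out = np.zeros_like(data)
        structure2d = np.ones((3, 3), dtype=bool)
        center2d = (np.asarray(data.shape[:2]) - 1) / 2.0
        for k in range(data.shape[2]):
            sl = data[:, :, k]
            if not sl.any():
                continue
            labels, n = ndimage.label(sl, structure=structure2d)
            out[:, :, k] = _keep_best_component(labels, n, center2d, score)
    elif mode == "volume":
        labels, n = ndimage.label(data, structure=np.ones((3, 3, 3), dtype=bool))
        center = (np.asarray(data.shape) - 1) / 2.0
        out = _keep_best_component(labels, n, center, score)
    else:
        raise ValueError(f"unknown component mode {mode!r}")
    return mask.with_data(out), False
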