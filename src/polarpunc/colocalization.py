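"""Pearson colocalization over square ROIs with a 90-degree rotation null.

The negative control rotates one channel's ROI by 90 degrees about the ROI
centre: punctate texture is preserved but spatial correspondence between the
channels is destroyed, so the rotated coefficient measures the chance
colocalization expected for unrelated structures of the same granularity.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DegenerateInputError, GeometryError


@dataclasses.dataclass
class ROI:
    """A square, fully-in-image region of interest.

    Physical sides are converted to an odd pixel count so the ROI has a
    centre pixel; explicitly pixel-sized ROIs may be even (the "centre" is
    then the upper-left pixel of the central 2x2).
    """

    id: int
    cx: int
    cy: int
    side_px: int

    def __post_init__(self):
        if self.side_px < 1:
            raise GeometryError("ROI side must be a positive pixel count")

    @property
    def half_lo(self) -> int:
        return (self.side_px - 1) // 2

    @property
    def half_hi(self) -> int:
        return self.side_px // 2

    def slices(self):
        return (slice(self.cy - self.half_lo, self.cy + self.half_hi + 1),
                slice(self.cx - self.half_lo, self.cx + self.half_hi + 1))

    def inside(self, shape_yx) -> bool:
        ny, nx = shape_yx
        return (self.cx - self.half_lo >= 0 and self.cy - self.half_lo >= 0
                and self.cx + self.half_hi < nx and self.cy + self.half_hi < ny)


@dataclasses.dataclass
class CorrResult:
    r: float
    n: int
    roi_id: int = -1
    is_null: bool = False


def side_um_to_px(side_um: float, pixel_size_um: float) -> int:
    """Physical ROI side to the nearest odd pixel count (centre pixel kept)."""
    n = int(round(side_um / pixel_size_um))
    if n < 1:
        n = 1
    if n % 2 == 0:
        n += 1 if (side_um / pixel_size_um) >= n else -1
    if n < 1:
        n = 1
    return n


def _extract(channel: np.ndarray, roi: Optional[ROI]) -> np.ndarray:
    arr = np.asarray(channel, dtype=float)
    if roi is None:
        return arr
    if not roi.inside(arr.shape):
        raise GeometryError("ROI extends outside the image")
    ys, xs = roi.slices()
    return arr[ys, xs]


def pearson(ch1: np.ndarray, ch2: np.ndarray,
            roi: Optional[ROI] = None) -> CorrResult:
    """Pearson correlation of the flattened ROI pixels of two channels."""
    a = _extract(ch1, roi).ravel()
    b = _extract(ch2, roi).ravel()
    if a.shape != b.shape:
        raise GeometryError("channels differ in shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("zero variance in an ROI channel")
    r = float(np.corrcoef(a, b)[0, 1])
    return CorrResult(r, a.size, -1 if roi is None else roi.id, False)


def rotation_null(ch1: np.ndarray, ch2: np.ndarray,
                  roi: Optional[ROI] = None) -> CorrResult:
    """Pearson coefficient after rotating the second channel's ROI by 90 deg.

    Rotation is counterclockwise about the ROI centre; the ROI (or the raw
    patches, when called without one) must be square.
    """
    a = _extract(ch1, roi)
    b = _extract(ch2, roi)
    if a.shape != b.shape:
        raise GeometryError("channels differ in shape")
    if a.shape[0] != a.shape[1]:
        raise GeometryError("rotation null needs a square ROI")
    b = np.rot90(b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("zero variance in an ROI channel")
    r = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
    return CorrResult(r, a.size, -1 if roi is None else roi.id, True)


def roi_grid(image_shape_yx, side_um: Optional[float] = None,
             pixel_size_um: float = 1.0,
             mask: Optional[np.ndarray] = None,
             side_px: Optional[int] = None) -> List[ROI]:
    """Non-overlapping tiling of square ROIs, optionally restricted to a mask.

    Pass either a physical side (``side_um``, rounded to an odd pixel
    count) or an explicit ``side_px``.  With a mask, an ROI is kept only
    when it lies entirely inside the mask.  Deterministic row-major order.
    """
    ny, nx = image_shape_yx
    if side_px is None:
        if side_um is None:
            raise ValueError("give side_um or side_px")
        side_px = side_um_to_px(side_um, pixel_size_um)
    if side_px > min(ny, nx):
        raise GeometryError("ROI side exceeds image size")
    half_lo = (side_px - 1) // 2
    rois = []
    rid = 0
    for cy in range(half_lo, ny - (side_px - 1 - half_lo), side_px):
        for cx in range(half_lo, nx - (side_px - 1 - half_lo), side_px):
            roi = ROI(rid, cx, cy, side_px)
            if mask is not None:
                ys, xs = roi.slices()
                if not np.all(mask[ys, xs]):
                    continue
            rois.append(roi)
            rid += 1
    return rois


def roi_around_beads(beads: Sequence, side_um: float, pixel_size_um: float,
                     image_shape_yx) -> List[ROI]:
    """Bead-centred square ROIs; border beads are dropped with a warning."""
    side = side_um_to_px(side_um, pixel_size_um)
    rois = []
    for b in beads:
        roi = ROI(getattr(b, "id", len(rois)), int(round(b.x_px)),
                  int(round(b.y_px)), side)
        if roi.inside(image_shape_yx):
            rois.append(roi)
        else:
            warnings.warn(f"bead {roi.id}: ROI outside image, dropped")
    return rois


def coloc_table(ch1: np.ndarray, ch2: np.ndarray,
                rois: Sequence[ROI]) -> pd.DataFrame:
    """Pearson r and rotation-null r for every ROI (degenerate ROIs skipped)."""
    rows = []
    for roi in rois:
        try:
            res = pearson(ch1, ch2, roi)
            null = rotation_null(ch1, ch2, roi)
        except DegenerateInputError:
            continue
        rows.append((roi.id, res.r, null.r, res.n))
    return pd.DataFrame(rows, columns=("roi_id", "r", "r_null", "n"))
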