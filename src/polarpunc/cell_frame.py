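"""Mapping lab-frame measurements into the cell's polarity coordinates.

A migrating cell defines a front-rear axis.  A point's relative position is
its projection onto the front-rear line, as a fraction of cell length:
``p`` runs rear = 0 to front = 1 (the convention used for density maps) and
``q = 1 - p`` is the distance from the front (the convention in which the
appearance/extinction statistics are quoted).  Projections falling outside
[0, 1] (points beyond the anchors) are clamped and flagged, not dropped.

Anchors are found automatically: the smoothed centroid velocity orients the
axis and the front/rear are the contour points with extremal projection onto
the heading.  A manual-anchor table overrides automation per frame.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label

from .core import (
    AmbiguousPolarityError,
    EmptyInputError,
    FrameMismatchError,
    GeometryError,
    ImageStack,
    NoCellError,
)
from .synthetic_scene import CellState


@dataclasses.dataclass
class RelPos:
    """Position along the polarity axis: p (rear=0, front=1), q = 1 - p."""

    p: float
    clamped: bool = False

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclasses.dataclass
class OutlineFrame:
    frame: int
    mask: Optional[np.ndarray]
    centroid: Tuple[float, float]
    front: Tuple[float, float]
    rear: Tuple[float, float]
    top: Tuple[float, float]
    bottom: Tuple[float, float]

    @property
    def length_px(self) -> float:
        f, r = np.asarray(self.front), np.asarray(self.rear)
        return float(np.hypot(*(f - r)))


class CellOutlineSeries:
    """Per-frame cell outline with polarity anchors, indexable by frame."""

    def __init__(self, frames: Sequence[OutlineFrame]):
        self._by_frame = {f.frame: f for f in frames}

    def __len__(self):
        return len(self._by_frame)

    def __contains__(self, frame):
        return frame in self._by_frame

    def __getitem__(self, frame: int) -> OutlineFrame:
        try:
            return self._by_frame[frame]
        except KeyError:
            raise FrameMismatchError(f"no outline for frame {frame}") from None

    def frames(self):
        return sorted(self._by_frame)

    @classmethod
    def from_cell_states(cls, states: Sequence[CellState]
                         ) -> "CellOutlineSeries":
        """Outline series from generator ground truth (exact anchors)."""
        return cls([OutlineFrame(s.frame, s.mask, s.centroid, s.front,
                                 s.rear, s.top, s.bottom) for s in states])


# ---------------------------------------------------------------------------
# segmentation and axis finding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SegmentationConfig:
    smooth_sigma: float = 1.0
    min_area_px: int = 200


def segment_cell(frame: np.ndarray,
                 config: Optional[SegmentationConfig] = None) -> np.ndarray:
    """Otsu threshold -> largest connected component -> hole filling."""
    cfg = config or SegmentationConfig()
    img = np.asarray(frame, dtype=float)
    if np.ptp(img) == 0:
        raise NoCellError("frame is constant; nothing to segment")
    if cfg.smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.smooth_sigma)
    mask = img > threshold_otsu(img)
    lab = label(mask)
    if lab.max() == 0:
        raise NoCellError("no foreground component")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    biggest = int(np.argmax(sizes))
    if sizes[biggest] < cfg.min_area_px:
        raise NoCellError(
            f"largest component has {sizes[biggest]} px < {cfg.min_area_px}")
    return ndimage.binary_fill_holes(lab == biggest)


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    yy, xx = np.nonzero(mask)
    return np.array([xx.mean(), yy.mean()])


def _largest_contour(mask: np.ndarray) -> np.ndarray:
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise NoCellError("mask has no contour")
    cont = max(contours, key=len)
    return cont[:, ::-1]  # (row, col) -> (x, y)


def find_axis(masks: Sequence[np.ndarray], velocity_smoothing: int = 5,
              manual_anchors: Optional[pd.DataFrame] = None,
              min_speed_px_frame: float = 0.05) -> CellOutlineSeries:
    """Locate front/rear and top/bottom anchors for every frame.

    The centroid velocity (boxcar-smoothed over ``velocity_smoothing``
    frames) gives the heading; the front is the contour point with maximal
    projection onto it, the rear minimal, and top/bottom likewise for the
    orthogonal direction.  A ``manual_anchors`` table (columns frame,
    front_x, front_y, rear_x, rear_y[, top_x, top_y, bottom_x, bottom_y])
    overrides per frame.  Raises :class:`AmbiguousPolarityError` when the
    cell barely moves and no manual anchors cover the gap.
    """
    n = len(masks)
    manual = {}
    if manual_anchors is not None:
        for _, r in manual_anchors.iterrows():
            manual[int(r["frame"])] = r
    if n < 2 and not manual:
        raise AmbiguousPolarityError("need >= 2 frames or manual anchors")

    centroids = np.array([_mask_centroid(m) for m in masks])
    if n >= 2:
        vel = np.gradient(centroids, axis=0)
        if velocity_smoothing > 1:
            vel = ndimage.uniform_filter1d(vel, size=velocity_smoothing,
                                           axis=0, mode="nearest")
        speeds = np.hypot(vel[:, 0], vel[:, 1])
    else:
        vel = np.zeros((n, 2))
        speeds = np.zeros(n)

    frames_out: List[OutlineFrame] = []
    for t in range(n):
        if t in manual:
            r = manual[t]
            front = (float(r["front_x"]), float(r["front_y"]))
            rear = (float(r["rear_x"]), float(r["rear_y"]))
            if "top_x" in r and not pd.isna(r.get("top_x")):
                top = (float(r["top_x"]), float(r["top_y"]))
                bottom = (float(r["bottom_x"]), float(r["bottom_y"]))
            else:
                top, bottom = _orthogonal_anchors(masks[t], front, rear)
            frames_out.append(OutlineFrame(t, masks[t],
                                           tuple(centroids[t]), front, rear,
                                           top, bottom))
            continue
        if speeds[t] < min_speed_px_frame:
            raise AmbiguousPolarityError(
                f"frame {t}: speed {speeds[t]:.3f} px/frame below "
                f"{min_speed_px_frame} and no manual anchors")
        heading = vel[t] / speeds[t]
        cont = _largest_contour(masks[t])
        proj = (cont - centroids[t]) @ heading
        front = _extremal_point(cont, proj, high=True)
        rear = _extremal_point(cont, proj, high=False)
        normal = np.array([-heading[1], heading[0]])
        orth = (cont - centroids[t]) @ normal
        top = _extremal_point(cont, orth, high=True)
        bottom = _extremal_point(cont, orth, high=False)
        frames_out.append(OutlineFrame(t, masks[t], tuple(centroids[t]),
                                       front, rear, top, bottom))
    return CellOutlineSeries(frames_out)


def _extremal_point(cont: np.ndarray, proj: np.ndarray, high: bool,
                    tol: float = 0.5):
    """Centroid of the contour points on the extremal projection plateau.

    Pixelated contours of smooth shapes have flat tips; averaging the
    near-extremal points recovers the tip centre instead of an arbitrary
    plateau corner.
    """
    if high:
        sel = proj >= proj.max() - tol
    else:
        sel = proj <= proj.min() + tol
    return tuple(cont[sel].mean(axis=0))


def _orthogonal_anchors(mask, front, rear):
    axis = np.asarray(front, dtype=float) - np.asarray(rear, dtype=float)
    axis = axis / np.hypot(*axis)
    normal = np.array([-axis[1], axis[0]])
    cont = _largest_contour(mask)
    c = _mask_centroid(mask)
    orth = (cont - c) @ normal
    return (_extremal_point(cont, orth, True),
            _extremal_point(cont, orth, False))


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _shift_int(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(img)
    ny, nx = img.shape
    xs_src = slice(max(0, -dx), min(nx, nx - dx))
    ys_src = slice(max(0, -dy), min(ny, ny - dy))
    xs_dst = slice(max(0, dx), min(nx, nx + dx))
    ys_dst = slice(max(0, dy), min(ny, ny + dy))
    out[ys_dst, xs_dst] = img[ys_src, xs_src]
    return out


def register_to_cell(stack: ImageStack, masks: Sequence[np.ndarray]):
    """Translate every frame so the cell's centre of mass stays put.

    Integer-pixel translations (the same for all channels) bring each
    frame's mask centroid onto the first frame's; returns the aligned stack
    and the (dx, dy) applied per frame.
    """
    ref = np.rint(_mask_centroid(masks[0]))
    data = np.empty_like(stack.data)
    translations = np.zeros((stack.n_frames, 2), dtype=int)
    for t in range(stack.n_frames):
        c = np.rint(_mask_centroid(masks[t]))
        dx, dy = int(ref[0] - c[0]), int(ref[1] - c[1])
        translations[t] = (dx, dy)
        for ch in range(stack.n_channels):
            data[t, ch] = _shift_int(stack.data[t, ch], dx, dy)
    aligned = ImageStack(data, stack.pixel_size_um, stack.frame_interval_s,
                         stack.channel_names)
    return aligned, translations


# ---------------------------------------------------------------------------
# relative positions
# ---------------------------------------------------------------------------

def relative_position(point, front, rear) -> RelPos:
    """Projection of a point onto the rear->front axis as a fraction.

    ``p = ((point - rear) . (front - rear)) / |front - rear|^2``, clamped to
    [0, 1] with the clamp flagged; the off-axis component is ignored.
    """
    front = np.asarray(front, dtype=float)
    rear = np.asarray(rear, dtype=float)
    d = front - rear
    n2 = float(d @ d)
    if n2 < 1e-12:
        raise GeometryError("front and rear anchors coincide")
    p = float((np.asarray(point, dtype=float) - rear) @ d / n2)
    clamped = not (0.0 <= p <= 1.0)
    return RelPos(min(max(p, 0.0), 1.0), clamped)


def relative_position_y(point, top, bottom) -> float:
    """As :func:`relative_position` along bottom (0) -> top (1)."""
    return relative_position(point, top, bottom).p


# ---------------------------------------------------------------------------
# position statistics
# ---------------------------------------------------------------------------

def spatial_histogram(detections: pd.DataFrame, masks: Sequence[np.ndarray],
                      n_bins: int = 10) -> np.ndarray:
    """Puncta density across the cell's x extent, pooled over frames.

    Assumes cells oriented along x (left to right); per frame the mask's x
    range is split into ``n_bins`` equal bins and each detection is assigned
    by its x coordinate.  Counts are pooled and normalized to sum to 1.
    """
    if len(detections) == 0:
        raise EmptyInputError("no detections to histogram")
    counts = np.zeros(n_bins)
    for t, grp in detections.groupby("frame"):
        t = int(t)
        mask = masks[t]
        cols = np.nonzero(mask.any(axis=0))[0]
        if cols.size == 0:
            continue
        lo, hi = cols.min() - 0.5, cols.max() + 0.5
        width = (hi - lo) / n_bins
        idx = np.clip(((grp["x_px"] - lo) / width).astype(int), 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("no detections fell inside mask frames")
    return counts / total


def histogram_on_cell(density: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Paint a 1-D density across a representative mask (display utility).

    Values outside the cell are NaN so the background plots white.
    """
    out = np.full(mask.shape, np.nan)
    cols = np.nonzero(mask.any(axis=0))[0]
    lo, hi = cols.min() - 0.5, cols.max() + 0.5
    width = (hi - lo) / density.size
    for j in cols:
        b = int(np.clip((j - lo) / width, 0, density.size - 1))
        col_mask = mask[:, j]
        out[col_mask, j] = density[b]
    return out


def event_positions(tracks, outline_series: CellOutlineSeries,
                    frame_interval_s: float = 1.0,
                    subframe_disappearance: bool = False) -> pd.DataFrame:
    """Appearance/disappearance positions (q, distance from front) per track.

    The first and last detection of each track are mapped through
    :func:`relative_position` using the outline of their own frames.
    With ``subframe_disappearance`` the extinction position is extrapolated
    half a frame beyond the last detection (at the track's final relative
    drift rate): a punctum vanishes somewhere between its last frame and
    the next, so the interval midpoint is the median-unbiased estimate of
    the extinction threshold, removing the half-frame sampling bias of the
    last-frame convention.
    """
    rows = []
    for tr in tracks:
        f0, f1 = tr.birth_frame, tr.death_frame
        o0, o1 = outline_series[f0], outline_series[f1]
        p_first = tr.positions[0]
        p_last = tr.positions[-1]
        r0 = relative_position(p_first, o0.front, o0.rear)
        r1 = relative_position(p_last, o1.front, o1.rear)
        q1 = r1.q
        if subframe_disappearance and len(tr) >= 2:
            f_prev = int(tr.frames[-2])
            o_prev = outline_series[f_prev]
            q_prev = relative_position(tr.positions[-2], o_prev.front,
                                       o_prev.rear).q
            rate = (q1 - q_prev) / (f1 - f_prev)
            q1 = float(np.clip(q1 + 0.5 * rate, 0.0, 1.0))
        rows.append((tr.id, f0, r0.q, f1, q1,
                     (f1 - f0 + 1) * frame_interval_s,
                     r0.clamped or r1.clamped))
    return pd.DataFrame(rows, columns=("track_id", "appear_frame", "appear_q",
                                       "disappear_frame", "disappear_q",
                                       "lifetime_s", "clamped"))


def cdf(values) -> pd.DataFrame:
    """Right-continuous empirical CDF as a (value, cdf) table."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise EmptyInputError("empty sample")
    return pd.DataFrame({
        "value": values,
        "cdf": np.arange(1, values.size + 1) / values.size,
    })


def fraction_by(values, q_star: float) -> float:
    """Empirical CDF evaluated at ``q_star`` (fraction of values <= q*)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("empty sample")
    return float(np.count_nonzero(values <= q_star) / values.size)
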