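"""Marker signal at substrate-attached beads, normalized per surface area.

Beads of known diameter deform the plasma membrane of a cell crawling over
them; curvature-sensing markers accumulate there.  The quantification chain:
detect (or load) stationary bead positions, restrict to beads completely
under the cell, fit a 2-D Gaussian to the marker signal at each bead
(volume ``2*pi*A*sx*sy``, background independent), and normalize by the full
sphere surface ``pi*d^2`` so different bead sizes are compared per unit
membrane area.  Position-resolved profiles track each bead's signal against
its cell-frame position q, normalized to the bead's own maximum.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from .core import (
    DegenerateInputError,
    EmptyInputError,
    GeometryError,
    ImageStack,
    robust_sd,
)
from .puncta_detection import (
    DetectionConfig,
    GaussianFit,
    detect_frame,
    fit_gaussian_2d,
    gaussian_volume,
)


@dataclasses.dataclass
class BeadSpec:
    """A substrate-attached bead: lab position (stationary) and diameter."""

    id: int
    x_px: float
    y_px: float
    diameter_nm: float

    def __post_init__(self):
        if not self.diameter_nm > 0 and not np.isnan(self.diameter_nm):
            raise ValueError("bead diameter must be > 0")

    def radius_px(self, pixel_size_um: float) -> float:
        return (self.diameter_nm / 1000.0) / (2.0 * pixel_size_um)


# ---------------------------------------------------------------------------
# bead localization and selection
# ---------------------------------------------------------------------------

def detect_beads(bead_channel_frame: np.ndarray,
                 config: Optional[DetectionConfig] = None,
                 diameter_nm: float = np.nan) -> List[BeadSpec]:
    """Detect beads on a single reference frame of the bead channel.

    Bead positions are assumed stationary thereafter.  Returns an empty list
    for a blank channel.
    """
    cfg = config or DetectionConfig()
    rows = detect_frame(np.asarray(bead_channel_frame, dtype=float), cfg)
    return [BeadSpec(i, x, y, diameter_nm)
            for i, (x, y, *_rest) in enumerate(rows)]


def beads_under_cell(beads: Sequence[BeadSpec], mask: np.ndarray,
                     pixel_size_um: float, margin_px: int = 3
                     ) -> List[BeadSpec]:
    """Keep beads completely under the cell.

    A bead is kept when its centre lies inside the mask eroded by its own
    radius (in px) plus ``margin_px``.
    """
    mask = np.asarray(mask, dtype=bool)
    out = []
    eroded_cache = {}
    for b in beads:
        r = int(np.ceil(b.radius_px(pixel_size_um))) + int(margin_px)
        if r not in eroded_cache:
            eroded_cache[r] = ndimage.binary_erosion(mask, iterations=max(r, 1))
        er = eroded_cache[r]
        iy, ix = int(round(b.y_px)), int(round(b.x_px))
        if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and er[iy, ix]:
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# per-bead quantification
# ---------------------------------------------------------------------------

def bead_fit(signal_frame: np.ndarray, bead: BeadSpec, window: int = 9,
             max_sigma: float = 6.0) -> GaussianFit:
    """2-D Gaussian fit to the marker signal centred on a bead."""
    return fit_gaussian_2d(signal_frame, (bead.x_px, bead.y_px), window,
                           max_sigma)


def bead_gaussian_volume(signal_frame: np.ndarray, bead: BeadSpec,
                         window: int = 9, max_sigma: float = 6.0) -> float:
    """Gaussian volume of the marker signal at a bead; NaN if the fit fails.

    The NaN fit-failure marker propagates into :func:`fraction_positive`
    rather than raising, mirroring how unfittable beads are counted as
    negatives instead of being discarded.
    """
    fit = bead_fit(signal_frame, bead, window, max_sigma)
    if not fit.converged:
        return np.nan
    return gaussian_volume(fit)


def per_area(volume: float, diameter_nm: float) -> float:
    """Signal per unit bead surface area: ``volume / (pi * d^2)``."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    return volume / (np.pi * diameter_nm ** 2)


def fraction_positive(signal_frames: Sequence[np.ndarray],
                      beads: Sequence[BeadSpec], window: int = 9,
                      max_sigma: float = 6.0, min_amplitude_snr: float = 4.0
                      ) -> Tuple[float, List[bool]]:
    """Fraction of beads at which the marker forms a fittable punctum.

    For each bead the brightest frame (by a small box sum) is fitted; the
    bead is positive when the fit converges with amplitude at least
    ``min_amplitude_snr`` times a robust frame-noise estimate.
    """
    if len(beads) == 0:
        raise EmptyInputError("no beads supplied")
    flags = []
    for b in beads:
        sums = [box_sum(fr, b, box_px=window) for fr in signal_frames]
        best = int(np.argmax(sums))
        frame = np.asarray(signal_frames[best], dtype=float)
        noise = robust_sd(frame - ndimage.median_filter(frame, size=5))
        fit = bead_fit(frame, b, window, max_sigma)
        flags.append(bool(fit.converged
                          and fit.amplitude >= min_amplitude_snr * noise))
    return float(np.mean(flags)), flags


def integrated_bg_subtracted(signal_frame: np.ndarray,
                             bead_mask: np.ndarray) -> float:
    """Foreground sum after subtracting the mean background pixel.

    ``bead_mask`` splits the frame (or ROI) into foreground (True) and
    background; returns ``sum(foreground - mean(background))``.
    """
    frame = np.asarray(signal_frame, dtype=float)
    mask = np.asarray(bead_mask, dtype=bool)
    if mask.shape != frame.shape:
        raise GeometryError("bead mask shape differs from frame")
    if not mask.any():
        raise EmptyInputError("empty foreground mask")
    bg = frame[~mask]
    if bg.size == 0:
        raise DegenerateInputError("mask leaves no background pixels")
    return float(np.sum(frame[mask] - bg.mean()))


def box_sum(signal_frame: np.ndarray, bead: BeadSpec, box_px: int = 9
            ) -> float:
    """Raw intensity sum in a small box around the bead.

    Absolute scale is irrelevant downstream: profiles are normalized to each
    bead's own maximum.
    """
    frame = np.asarray(signal_frame, dtype=float)
    half = box_px // 2
    iy, ix = int(round(bead.y_px)), int(round(bead.x_px))
    ny, nx = frame.shape
    if ix - half < 0 or iy - half < 0 or ix + half >= nx or iy + half >= ny:
        raise GeometryError("box extends outside the frame")
    return float(frame[iy - half:iy + half + 1,
                       ix - half:ix + half + 1].sum())


# ---------------------------------------------------------------------------
# traces and profiles
# ---------------------------------------------------------------------------

def local_background(frame: np.ndarray, bead: BeadSpec, box_px: int = 9,
                     pad_px: int = 4,
                     valid_mask: Optional[np.ndarray] = None) -> float:
    """Median pixel of the ring around the bead box (cytoplasm level).

    ``valid_mask`` restricts the ring to trustworthy background pixels
    (e.g. the cell interior, away from the dimmer membrane edge).
    """
    half = box_px // 2 + pad_px
    iy, ix = int(round(bead.y_px)), int(round(bead.x_px))
    ny, nx = frame.shape
    ylo, yhi = max(0, iy - half), min(ny, iy + half + 1)
    xlo, xhi = max(0, ix - half), min(nx, ix + half + 1)
    win = frame[ylo:yhi, xlo:xhi].astype(float).copy()
    if valid_mask is not None:
        win[~valid_mask[ylo:yhi, xlo:xhi]] = np.nan
    inner = box_px // 2
    win[max(0, iy - inner - ylo):iy + inner + 1 - ylo,
        max(0, ix - inner - xlo):ix + inner + 1 - xlo] = np.nan
    ring = win[~np.isnan(win)]
    return float(np.median(ring)) if ring.size else 0.0


def bead_traces(stack: ImageStack, channel: int, beads: Sequence[BeadSpec],
                outline_series, box_px: int = 9, fit_window: int = 9
                ) -> pd.DataFrame:
    """Per-frame (q, box sums, Gaussian volume) for each stationary bead.

    ``box_sum`` is the raw sum; ``box_sum_bg`` subtracts the local median
    background (the cytoplasm around the bead) times the box area, which is
    the robust choice when the diffuse cytoplasmic signal rivals the
    bead-recruited signal.
    """
    from .cell_frame import relative_position  # deferred: avoids import cycle

    rows = []
    area = box_px * box_px
    # "completely under the cell": box AND background ring must be inside,
    # or edge-crossing frames corrupt the local-background estimate
    margin = box_px // 2 + 5
    eroded = {}
    for b in beads:
        for t in range(stack.n_frames):
            o = outline_series[t]
            rel = relative_position((b.x_px, b.y_px), o.front, o.rear)
            if t not in eroded:
                eroded[t] = None if o.mask is None else ndimage.binary_erosion(
                    o.mask.astype(bool), iterations=margin)
            under = eroded[t] is not None \
                and eroded[t][int(round(b.y_px)), int(round(b.x_px))] \
                and not rel.clamped
            frame = stack.frame(t, channel).astype(float)
            try:
                s = box_sum(frame, b, box_px)
            except GeometryError:
                continue
            s_bg = s - area * local_background(frame, b, box_px,
                                               valid_mask=eroded[t])
            vol = bead_gaussian_volume(frame, b, fit_window) if under else np.nan
            rows.append((b.id, t, rel.q, s, s_bg, vol, under))
    return pd.DataFrame(rows, columns=("bead_id", "frame", "q", "box_sum",
                                       "box_sum_bg", "volume", "under_cell"))


def bead_profile(traces: pd.DataFrame, bin_width: float = 0.1,
                 value_col: str = "box_sum"):
    """Population profile of normalized bead signal versus position q.

    Each bead's signal is normalized to its own maximum; q is discretized to
    the nearest ``bin_width``; a per-bead bin mean is averaged across beads.
    Returns ``(profile, points)``: the profile table (q_bin,
    mean_norm_signal, n_points) and the per-point table with a
    kernel-density weight of each value among all values in its bin (for
    plotting point clouds under the line).
    """
    pts = []
    for bead_id, grp in traces.groupby("bead_id"):
        grp = grp[grp["under_cell"]] if "under_cell" in grp else grp
        if len(grp) == 0:
            continue
        peak = grp[value_col].max()
        if not np.isfinite(peak) or peak <= 0:
            raise DegenerateInputError(f"bead {bead_id}: zero-max trace")
        sub = grp.assign(
            norm=grp[value_col] / peak,
            q_bin=np.round(np.round(grp["q"] / bin_width) * bin_width, 10))
        if sub["q_bin"].nunique() < 2:
            raise DegenerateInputError(
                f"bead {bead_id} visits fewer than 2 position bins")
        pts.append(sub)
    if not pts:
        raise EmptyInputError("no usable traces")
    points = pd.concat(pts, ignore_index=True)

    per_bead_bin = points.groupby(["bead_id", "q_bin"])["norm"].mean()
    profile = per_bead_bin.groupby("q_bin").mean().rename("mean_norm_signal")
    n_points = points.groupby("q_bin")["norm"].size().rename("n_points")
    profile = pd.concat([profile, n_points], axis=1).reset_index()

    kde_w = np.ones(len(points))
    for _, idx in points.groupby("q_bin").groups.items():
        vals = points.loc[idx, "norm"].to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 1e-12:
            kde = gaussian_kde(vals)
            kde_w[points.index.get_indexer(idx)] = kde(vals)
    points = points.assign(kde_weight=kde_w)
    return profile, points


def gain_loss(trace: pd.DataFrame, value_col: str = "box_sum",
              noise_floor: float = 0.0) -> pd.DataFrame:
    """Classify consecutive-frame signal changes as gain or loss versus q.

    Returns rows (q_mid, delta, label) for intervals whose |delta| exceeds
    ``noise_floor``; a constant trace yields no classified intervals.
    """
    if len(trace) < 2:
        raise EmptyInputError("trace needs at least 2 frames")
    trace = trace.sort_values("frame")
    v = trace[value_col].to_numpy(dtype=float)
    q = trace["q"].to_numpy(dtype=float)
    dv = np.diff(v)
    qm = 0.5 * (q[:-1] + q[1:])
    keep = np.abs(dv) > noise_floor
    labels = np.where(dv > 0, "gain", "loss")
    return pd.DataFrame({"q_mid": qm[keep], "delta": dv[keep],
                         "label": labels[keep]})
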