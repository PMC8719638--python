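"""Whole-cell migration metrics from nucleus tracks.

Metrics follow the conventions used for under-agarose migration assays:

* tracks are kept only if they last at least half the movie and are present
  throughout the first half, and all metrics are computed over that common
  first-half window so every lag averages the same cells;
* MSD is the ensemble mean of ``|x(t) - x(0)|^2`` (no time averaging);
* the persistence ratio is net displacement over total path length per
  window (the printed-formula variant with a displacement-from-origin
  denominator is available behind a flag);
* the alignment ratio (contact guidance) is total distance along the
  pattern axis over total distance perpendicular to it, per cell.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import InsufficientDataError


@dataclasses.dataclass
class NucleusTrack:
    """One cell's nucleus positions over time (micrometres)."""

    cell_id: str
    frames: np.ndarray
    xy_um: np.ndarray
    condition: str = ""
    replicate: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if self.frames.ndim != 1 or self.xy_um.shape != (self.frames.size, 2):
            raise ValueError("frames must be 1-D and xy (n, 2)")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.xy_um)):
            raise ValueError("positions must be finite")

    @property
    def duration(self) -> int:
        return int(self.frames[-1] - self.frames[0] + 1)


def tracks_from_table(df: pd.DataFrame, pixel_size_um: float = 1.0,
                      condition: str = "", replicate: str = ""
                      ) -> List[NucleusTrack]:
    """Build tracks from a (track_id, frame, x_px, y_px) table."""
    out = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        out.append(NucleusTrack(str(tid), grp["frame"].to_numpy(),
                                grp[["x_px", "y_px"]].to_numpy() * pixel_size_um,
                                condition, replicate))
    return out


def filter_cell_tracks(tracks: Sequence[NucleusTrack], movie_length: int
                       ) -> List[NucleusTrack]:
    """Keep tracks lasting >= half the movie and covering the first half.

    Kept tracks are trimmed to the common first-half window so downstream
    metrics compare every cell over the same time span.
    """
    if movie_length < 2:
        raise ValueError("movie_length must be >= 2")
    half = movie_length // 2
    out = []
    for tr in tracks:
        if tr.duration < movie_length / 2:
            continue
        if tr.frames[0] > 0 or tr.frames[-1] < half - 1:
            continue
        sel = tr.frames <= half - 1
        out.append(NucleusTrack(tr.cell_id, tr.frames[sel], tr.xy_um[sel],
                                tr.condition, tr.replicate))
    return out


def total_distance(track: NucleusTrack) -> Tuple[float, float, float]:
    """Summed step lengths: total Euclidean, and per-axis |dx|, |dy| sums."""
    if len(track.frames) < 2:
        raise InsufficientDataError("need >= 2 points")
    steps = np.diff(track.xy_um, axis=0)
    total = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    return total, float(np.sum(np.abs(steps[:, 0]))), \
        float(np.sum(np.abs(steps[:, 1])))


def alignment_ratio(tracks: Sequence[NucleusTrack],
                    pattern_axis_rad: float = 0.0) -> pd.DataFrame:
    """Aligned/perpendicular total distance per cell (contact guidance).

    Coordinates are rotated so the pattern axis is x.  Cells with zero
    perpendicular distance have an undefined ratio and are excluded with a
    warning.  Replicate-level aggregation is the mean of cell ratios.
    """
    c, s = np.cos(-pattern_axis_rad), np.sin(-pattern_axis_rad)
    rot = np.array([[c, -s], [s, c]])
    rows = []
    for tr in tracks:
        r = NucleusTrack(tr.cell_id, tr.frames, tr.xy_um @ rot.T,
                         tr.condition, tr.replicate)
        _, tx, ty = total_distance(r)
        if ty == 0:
            warnings.warn(f"cell {tr.cell_id}: zero perpendicular distance, "
                          "alignment ratio undefined; excluded")
            continue
        rows.append((tr.cell_id, tr.replicate, tr.condition, tx / ty))
    return pd.DataFrame(rows, columns=("cell_id", "replicate", "condition",
                                       "ratio"))


def msd(tracks: Sequence[NucleusTrack], return_per_cell: bool = False):
    """Ensemble MSD: mean over cells of ``|x(t) - x(0)|^2`` at each lag.

    Lags are frame offsets from each track's first frame; a lag averages the
    tracks that reach it.  No time averaging.
    """
    if not tracks:
        raise InsufficientDataError("no tracks")
    max_lag = max(tr.frames[-1] - tr.frames[0] for tr in tracks)
    lags = np.arange(max_lag + 1)
    per_cell = np.full((len(tracks), max_lag + 1), np.nan)
    for i, tr in enumerate(tracks):
        rel = tr.frames - tr.frames[0]
        disp = tr.xy_um - tr.xy_um[0]
        per_cell[i, rel] = disp[:, 0] ** 2 + disp[:, 1] ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(per_cell, axis=0)
    n = np.sum(~np.isnan(per_cell), axis=0)
    df = pd.DataFrame({"lag": lags, "msd_um2": curve, "n": n})
    if return_per_cell:
        return df, per_cell
    return df


def persistence_ratio(tracks: Sequence[NucleusTrack],
                      printed_formula: bool = False,
                      return_per_cell: bool = False):
    """Net displacement over total path length, per window T, cell-averaged.

    With ``printed_formula=True`` the denominator is the sum of
    displacements from the origin (an alternative normalisation that is not
    a path length and is not bounded by 1); the default path-length form
    satisfies ratio <= 1 with equality only for straight monotone paths.
    Stationary windows (zero denominator) are excluded.
    """
    if not tracks:
        raise InsufficientDataError("no tracks")
    max_lag = max(tr.frames[-1] - tr.frames[0] for tr in tracks)
    per_cell = np.full((len(tracks), max_lag + 1), np.nan)
    for i, tr in enumerate(tracks):
        if len(tr.frames) < 2:
            raise InsufficientDataError(f"track {tr.cell_id} has < 2 points")
        rel = tr.frames - tr.frames[0]
        disp = np.hypot(*(tr.xy_um - tr.xy_um[0]).T)
        steps = np.hypot(*np.diff(tr.xy_um, axis=0).T)
        path = np.concatenate([[0.0], np.cumsum(steps)])
        if printed_formula:
            denom = np.cumsum(disp)
        else:
            denom = path
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(denom > 0, disp / denom, np.nan)
        per_cell[i, rel[1:]] = ratio[1:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(per_cell, axis=0)
    n = np.sum(~np.isnan(per_cell), axis=0)
    df = pd.DataFrame({"window": np.arange(max_lag + 1),
                       "persistence": curve, "n": n}).iloc[1:]
    if return_per_cell:
        return df.reset_index(drop=True), per_cell
    return df.reset_index(drop=True)


def bootstrap_ci(per_cell: np.ndarray, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> Tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap over cells of a per-cell curve matrix.

    ``per_cell`` is (cells x lags), NaN where a cell does not reach a lag.
    Returns (lower, upper) bounds per lag.
    """
    per_cell = np.asarray(per_cell, dtype=float)
    n_cells = per_cell.shape[0]
    if n_cells < 5:
        raise InsufficientDataError("bootstrap needs >= 5 cells")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_cells, size=(n_boot, n_cells))
    boots = np.empty((n_boot, per_cell.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_boot):
            boots[b] = np.nanmean(per_cell[idx[b]], axis=0)
    alpha = (1.0 - level) / 2.0
    lo = np.nanpercentile(boots, 100 * alpha, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha), axis=0)
    return lo, hi
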