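"""Frame-to-frame linking of detections into tracks, filtering and kymographs.

Linking solves, for every consecutive frame pair, the globally minimal-cost
one-to-one assignment with squared Euclidean cost; a link is forbidden beyond
``max_displacement`` and every unlinked endpoint pays ``max_displacement**2``
(the standard augmented linear-assignment construction, so linking within
range is always preferred over a birth plus a death).  Optional gap closing
joins a track end to a later track start within ``max_gap`` skipped frames at
a proportionally enlarged radius.

Substrate-fixed versus flowing classification thresholds the mean per-frame
lab displacement of a track at ``stationary_epsilon``.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .core import GeometryError, ImageStack, InsufficientDataError

_FORBIDDEN = 1e12


@dataclasses.dataclass
class LinkConfig:
    # Substrate-fixed puncta only jitter by localization error (~0.3 px), so
    # the default link radius is tight; raise it for flowing puncta (EDTA) or
    # drifting samples.  It also bounds the gap-closing radius
    # (max_displacement * (gap + 1)), which must stay below the typical
    # punctum spacing or gap closing will chain distinct events together.
    max_displacement: float = 1.5      # px per frame
    max_gap: int = 0                   # frames that may be skipped
    min_duration: int = 2              # frames
    stationary_epsilon: float = 0.5    # px per frame

    def __post_init__(self):
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.stationary_epsilon < 0:
            raise ValueError("stationary_epsilon must be >= 0")


@dataclasses.dataclass
class Track:
    """An ordered sequence of detections belonging to one punctum."""

    id: int
    detections: pd.DataFrame    # detection rows, sorted by frame
    touches_movie_boundary: bool = False

    @property
    def frames(self) -> np.ndarray:
        return self.detections["frame"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.detections[["x_px", "y_px"]].to_numpy(dtype=float)

    @property
    def birth_frame(self) -> int:
        return int(self.frames[0])

    @property
    def death_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def duration(self) -> int:
        return self.death_frame - self.birth_frame + 1

    def __len__(self) -> int:
        return len(self.detections)


def _pair_assignment(prev_xy: np.ndarray, next_xy: np.ndarray,
                     max_disp: float) -> List[Tuple[int, int]]:
    """Min-cost one-to-one links between two point sets (augmented LAP)."""
    n, m = len(prev_xy), len(next_xy)
    if n == 0 or m == 0:
        return []
    d2 = np.sum((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2, axis=2)
    alt = max_disp ** 2
    link = np.where(d2 <= alt, d2, _FORBIDDEN)
    size = n + m
    cost = np.full((size, size), _FORBIDDEN)
    cost[:n, :m] = link
    cost[np.arange(n), m + np.arange(n)] = alt          # deaths
    cost[n + np.arange(m), np.arange(m)] = alt          # births
    cost[n:, m:] = 0.0                                  # slack block
    rows, cols = linear_sum_assignment(cost)
    out = []
    for r, c in zip(rows, cols):
        if r < n and c < m and link[r, c] < _FORBIDDEN:
            out.append((r, c))
    return out


def link(detections: pd.DataFrame, config: LinkConfig) -> List[Track]:
    """Link a detection table into tracks.

    Detections must carry columns (frame, x_px, y_px); every detection ends
    up in exactly one track.  Deterministic: scipy's Hungarian solver plus a
    stable ordering of detections.
    """
    if len(detections) == 0:
        return []
    det = detections.sort_values(["frame", "y_px", "x_px"],
                                 kind="mergesort").reset_index(drop=True)
    frames = det["frame"].to_numpy()
    chains: List[List[int]] = []       # lists of row indices
    open_by_frame = {}                 # frame -> list of chain indices

    for f in np.unique(frames):
        idx = np.nonzero(frames == f)[0]
        xy = det.loc[idx, ["x_px", "y_px"]].to_numpy(dtype=float)
        prev_chains = open_by_frame.pop(f - 1, [])
        matched_next = set()
        if prev_chains:
            prev_xy = np.array([det.loc[chains[c][-1], ["x_px", "y_px"]]
                                for c in prev_chains], dtype=float)
            for r, c in _pair_assignment(prev_xy, xy,
                                         config.max_displacement):
                chains[prev_chains[r]].append(int(idx[c]))
                matched_next.add(c)
                open_by_frame.setdefault(f, []).append(prev_chains[r])
        for c, row in enumerate(idx):
            if c not in matched_next:
                chains.append([int(row)])
                open_by_frame.setdefault(f, []).append(len(chains) - 1)

    if config.max_gap > 0:
        chains = _close_gaps(chains, det, config)

    tracks = []
    order = sorted(range(len(chains)),
                   key=lambda c: (frames[chains[c][0]], chains[c][0]))
    for tid, c in enumerate(order):
        rows = det.loc[chains[c]].sort_values("frame", kind="mergesort")
        tracks.append(Track(tid, rows.reset_index(drop=True)))
    return tracks


def _close_gaps(chains, det, config: LinkConfig):
    frames = det["frame"].to_numpy()
    ends = []    # (chain idx, frame, x, y)
    starts = []
    for c, rows in enumerate(chains):
        f0, f1 = frames[rows[0]], frames[rows[-1]]
        starts.append((c, f0, det.at[rows[0], "x_px"], det.at[rows[0], "y_px"]))
        ends.append((c, f1, det.at[rows[-1], "x_px"], det.at[rows[-1], "y_px"]))
    n, m = len(ends), len(starts)
    alt = (config.max_displacement * (config.max_gap + 1)) ** 2
    link_cost = np.full((n, m), _FORBIDDEN)
    for i, (ci, fi, xi, yi) in enumerate(ends):
        for j, (cj, fj, xj, yj) in enumerate(starts):
            gap = fj - fi - 1
            if ci == cj or not (1 <= gap <= config.max_gap):
                continue
            radius = config.max_displacement * (gap + 1)
            d2 = (xi - xj) ** 2 + (yi - yj) ** 2
            if d2 <= radius ** 2:
                link_cost[i, j] = d2
    size = n + m
    cost = np.full((size, size), _FORBIDDEN)
    cost[:n, :m] = link_cost
    cost[np.arange(n), m + np.arange(n)] = alt
    cost[n + np.arange(m), np.arange(m)] = alt
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    merge_into = {}   # start chain -> end chain
    for r, c in zip(rows, cols):
        if r < n and c < m and link_cost[r, c] < _FORBIDDEN:
            merge_into[starts[c][0]] = ends[r][0]

    # resolve chains of merges end-to-start
    def root(c):
        while c in merge_into:
            c = merge_into[c]
        return c

    merged = {}
    for c, rows_ in enumerate(chains):
        merged.setdefault(root(c), []).extend(rows_)
    return [sorted(v, key=lambda r: frames[r]) for v in merged.values()]


def filter_tracks(tracks: Sequence[Track], config: LinkConfig,
                  movie_length: int, interior_only: bool = True
                  ) -> List[Track]:
    """Drop short tracks and, optionally, tracks touching the movie limits.

    Interior-events mode removes tracks that appear in frame 0 or persist to
    the final frame, whose true birth or death is unobserved.
    """
    if movie_length < 1:
        raise ValueError("movie_length must be >= 1")
    out = []
    for tr in tracks:
        tr.touches_movie_boundary = (tr.birth_frame == 0
                                     or tr.death_frame == movie_length - 1)
        if tr.duration < config.min_duration:
            continue
        if interior_only and tr.touches_movie_boundary:
            continue
        out.append(tr)
    return out


def lifetime(track: Track, frame_interval_s: float) -> float:
    """Track lifetime in seconds, endpoints inclusive."""
    if len(track) == 0:
        raise InsufficientDataError("empty track")
    return (track.death_frame - track.birth_frame + 1) * frame_interval_s


def classify_substrate_fixed(track: Track, config: LinkConfig):
    """Classify a track as substrate-fixed or flowing.

    Returns ``(label, mean_speed_px_frame, direction_rad)``; the label is
    ``"fixed"`` when the mean per-frame lab displacement is below
    ``stationary_epsilon``.
    """
    if len(track) < 3:
        raise InsufficientDataError("need at least 3 detections to classify")
    pos = track.positions
    fr = track.frames.astype(float)
    steps = np.diff(pos, axis=0)
    dfr = np.diff(fr)
    per_frame = steps / dfr[:, None]
    speed = float(np.mean(np.hypot(per_frame[:, 0], per_frame[:, 1])))
    net = pos[-1] - pos[0]
    direction = float(np.arctan2(net[1], net[0]))
    label = "fixed" if speed < config.stationary_epsilon else "flowing"
    return label, speed, direction


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Flatten tracks to a (track_id, frame, x_px, y_px, volume) table."""
    rows = []
    for tr in tracks:
        for _, d in tr.detections.iterrows():
            rows.append((tr.id, int(d["frame"]), d["x_px"], d["y_px"],
                         d.get("volume", np.nan)))
    return pd.DataFrame(rows, columns=("track_id", "frame", "x_px", "y_px",
                                       "volume"))


_TRACKER_ALIASES = {
    "track_id": "track_id", "trackid": "track_id", "id": "track_id",
    "position_x": "x_px", "x": "x_px", "x_px": "x_px",
    "position_y": "y_px", "y": "y_px", "y_px": "y_px",
    "frame": "frame", "t": "frame", "position_t": "frame",
}


def read_tracker_csv(path) -> pd.DataFrame:
    """Read a tracker-export CSV (TRACK_ID, POSITION_X, POSITION_Y, FRAME).

    Header-case and common alias variants are tolerated; non-numeric header
    repetition rows (as some exporters emit) are dropped.
    """
    df = pd.read_csv(path)
    renames = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "_")
        if key in _TRACKER_ALIASES:
            renames[col] = _TRACKER_ALIASES[key]
    df = df.rename(columns=renames)
    required = {"track_id", "x_px", "y_px", "frame"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracker CSV lacks columns: {sorted(missing)}")
    df = df[list(required & set(df.columns)) +
            [c for c in df.columns if c not in required]]
    for c in ("x_px", "y_px", "frame"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=["x_px", "y_px", "frame"])
    df["frame"] = df["frame"].astype(int)
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)


def kymograph(stack: ImageStack, channel: int,
              line_endpoints: Tuple[Tuple[float, float], Tuple[float, float]],
              width_px: int = 1) -> np.ndarray:
    """Intensity along a line over time: rows = positions, columns = frames.

    The line is sampled at ~1 px spacing with linear interpolation; across
    ``width_px`` parallel offset lines the maximum is taken.
    """
    (x0, y0), (x1, y1) = line_endpoints
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length < 1e-9:
        raise GeometryError("kymograph line has zero length")
    n_pos = int(np.ceil(length)) + 1
    ts = np.linspace(0.0, 1.0, n_pos)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    nxv, nyv = -uy, ux
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    out = np.empty((n_pos, stack.n_frames))
    for t in range(stack.n_frames):
        img = stack.frame(t, channel).astype(float)
        best = np.full(n_pos, -np.inf)
        for off in offsets:
            xs = x0 + ts * (x1 - x0) + off * nxv
            ys = y0 + ts * (y1 - y0) + off * nyv
            vals = ndimage.map_coordinates(img, [ys, xs], order=1,
                                           mode="nearest")
            best = np.maximum(best, vals)
        out[:, t] = best
    return out
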