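"""Hierarchical replicate statistics, file I/O, configuration and pipeline.

Statistics follow the replicate-aware convention for imaging experiments:
raw measurements nest in cells, cells in technical replicates, and tests are
run at the level (raw / cell / replicate) appropriate to the measurement.
Replicate means default to the pooled mean of that replicate's raw values; a
cell-mean-of-means mode is available.  Paired and unpaired two-tailed
t-tests are the comparison workhorses; no multiple-testing correction is
applied, and all p-values are reported with their test metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import stats as sstats

from .core import ConfigError, DegenerateInputError, EmptyInputError, ImageStack

logger = logging.getLogger("polarpunc")


# ---------------------------------------------------------------------------
# hierarchical aggregation and t-tests
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ("value", "cell_id", "replicate_id", "condition",
                       "measure")


def aggregate(measurements: pd.DataFrame, level: str,
              cell_mean_mode: bool = False) -> pd.DataFrame:
    """Aggregate a measurement table to raw / cell / replicate level.

    ``replicate`` level defaults to the pooled mean of the replicate's raw
    values; ``cell_mean_mode=True`` takes the mean of the replicate's cell
    means instead.
    """
    if level not in ("raw", "cell", "replicate"):
        raise ValueError(f"unknown aggregation level {level!r}")
    if len(measurements) == 0:
        raise EmptyInputError("empty measurement table")
    if level == "raw":
        return measurements.copy()
    group_cols = [c for c in ("condition", "measure") if c in measurements]
    if level == "cell":
        keys = group_cols + ["replicate_id", "cell_id"]
        out = measurements.groupby(keys, dropna=False)["value"].mean()
        return out.reset_index()
    keys = group_cols + ["replicate_id"]
    if cell_mean_mode:
        cells = aggregate(measurements, "cell")
        out = cells.groupby(keys, dropna=False)["value"].mean()
    else:
        out = measurements.groupby(keys, dropna=False)["value"].mean()
    return out.reset_index()


@dataclasses.dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    kind: str                  # "paired" | "unpaired"
    aggregation: str = "raw"   # level the inputs were aggregated at

    def __iter__(self):
        yield from (self.statistic, self.df, self.p_value)


def paired_t(x, y, aggregation: str = "raw") -> TestResult:
    """Classical paired two-tailed t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired test needs equal-length samples, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance of paired differences")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sstats.t.sf(abs(t), df))
    return TestResult(t, df, p, "paired", aggregation)


def unpaired_t(x, y, welch: bool = False,
               aggregation: str = "raw") -> TestResult:
    """Classical (pooled-variance) two-tailed t-test; Welch optional."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired test needs n >= 2 per group")
    res = sstats.ttest_ind(x, y, equal_var=not welch)
    if not np.isfinite(res.statistic):
        raise DegenerateInputError("degenerate unpaired test (zero variance)")
    return TestResult(float(res.statistic), float(res.df),
                      float(res.pvalue), "unpaired", aggregation)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path) -> None:
    """Write a TCYX TIFF plus a JSON sidecar with the physical calibration."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={"axes": "TCYX"},
                     photometric="minisblack")
    stack.save_sidecar(path.with_suffix(".json"))


def read_stack(path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:          # single channel stored without C axis
        data = data[:, None]
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ConfigError(f"missing sidecar metadata {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    return ImageStack(data, meta["pixel_size_um"], meta["frame_interval_s"],
                      tuple(meta.get("channel_names",
                                     [f"ch{i}" for i in range(data.shape[1])])))


def write_table(df: pd.DataFrame, path) -> None:
    # %.17g + round_trip parsing keeps float64 columns bitwise across a cycle
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path):
    """Load a YAML run configuration into per-stage config objects.

    Schema: top-level blocks ``scene``, ``detection``, ``linking`` (each a
    mapping of that stage's dataclass fields) and optional scalars ``seed``,
    ``n_cells``.  ``scene.pixel_size_um`` and ``scene.frame_interval_s``
    are required so physical units are always explicit.  Unknown fields and
    missing required fields raise :class:`ConfigError` naming the field.
    """
    from .puncta_detection import DetectionConfig
    from .puncta_tracking import LinkConfig
    from .synthetic_scene import SceneConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_blocks = {"scene", "detection", "linking", "seed", "n_cells"}
    for key in raw:
        if key not in known_blocks:
            raise ConfigError(f"unknown config block '{key}'")

    scene_raw = dict(raw.get("scene", {}))
    for required in ("pixel_size_um", "frame_interval_s"):
        if required not in scene_raw:
            raise ConfigError(f"scene.{required} is required")
    if "image_shape" in scene_raw:
        scene_raw["image_shape"] = tuple(scene_raw["image_shape"])

    def build(cls, block, name):
        fields = {f.name for f in dataclasses.fields(cls)}
        for key in block:
            if key not in fields:
                raise ConfigError(f"unknown field '{name}.{key}'")
        try:
            return cls(**block)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid '{name}' block: {exc}") from exc

    return {
        "scene": build(SceneConfig, scene_raw, "scene"),
        "detection": build(DetectionConfig, dict(raw.get("detection", {})),
                           "detection"),
        "linking": build(LinkConfig, dict(raw.get("linking", {})), "linking"),
        "seed": int(raw.get("seed", 0)),
        "n_cells": int(raw.get("n_cells", 1)),
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir, seed: Optional[int] = None) -> dict:
    """Simulate -> detect -> track -> cell-frame -> coloc -> migrate.

    Executes the whole chain on ``n_cells`` synthetic cells and writes every
    table, a couple of overview figures and a machine-readable
    ``summary.json`` into ``outdir``.  Fully deterministic for a given
    config and seed.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from . import cell_frame, colocalization, migration_stats
    from .puncta_detection import detect_stack
    from .puncta_tracking import filter_tracks, link, tracks_to_frame
    from .synthetic_scene import simulate_scene

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene_cfg = config["scene"]
    det_cfg = config["detection"]
    link_cfg = config["linking"]
    base_seed = int(config.get("seed", 0) if seed is None else seed)
    n_cells = int(config.get("n_cells", 1))

    timings = {}
    summary = {"seed": base_seed, "n_cells": n_cells, "stages": {}}

    all_events = []
    all_tracks_tables = []
    nucleus_tracks = []
    t0 = time.perf_counter()
    for i in range(n_cells):
        cell_seed = base_seed + i
        stack, gt = simulate_scene(scene_cfg, cell_seed)
        if i == 0:
            write_stack(stack, outdir / "scene.tif")
            gt.write(outdir)
        masks = [s.mask for s in gt.cell_states]
        det = detect_stack(stack, 0, det_cfg, masks=masks)
        tracks = link(det, link_cfg)
        kept = filter_tracks(tracks, link_cfg, stack.n_frames)
        outline = cell_frame.CellOutlineSeries.from_cell_states(gt.cell_states)
        ev = cell_frame.event_positions(kept, outline,
                                        scene_cfg.frame_interval_s)
        ev.insert(0, "cell", i)
        all_events.append(ev)
        tt = tracks_to_frame(kept)
        tt.insert(0, "cell", i)
        all_tracks_tables.append(tt)
        centroids = np.array([s.centroid for s in gt.cell_states])
        nucleus_tracks.append(migration_stats.NucleusTrack(
            str(i), np.arange(len(centroids)),
            centroids * scene_cfg.pixel_size_um))
        if i == 0:
            # colocalization on the middle frame of the first cell
            mid = stack.n_frames // 2
            rois = colocalization.roi_grid(stack.shape_yx, 1.5,
                                           scene_cfg.pixel_size_um,
                                           mask=masks[mid])
            ctab = colocalization.coloc_table(
                stack.frame(mid, 0).astype(float),
                stack.frame(mid, 1).astype(float), rois)
            write_table(ctab, outdir / "coloc.csv")
            summary["stages"]["coloc"] = {
                "n_rois": int(len(ctab)),
                "mean_r": float(ctab["r"].mean()) if len(ctab) else None,
                "mean_r_null": float(ctab["r_null"].mean())
                if len(ctab) else None,
            }
    timings["scenes_and_detection_s"] = round(time.perf_counter() - t0, 2)

    events = pd.concat(all_events, ignore_index=True)
    write_table(events, outdir / "events.csv")
    write_table(pd.concat(all_tracks_tables, ignore_index=True),
                outdir / "tracks.csv")

    summary["stages"]["events"] = {
        "n_tracks": int(len(events)),
        "mean_appear_q": float(events["appear_q"].mean()),
        "mean_disappear_q": float(events["disappear_q"].mean()),
        "fraction_gone_by_half": cell_frame.fraction_by(
            events["disappear_q"], 0.5),
        "mean_lifetime_s": float(events["lifetime_s"].mean()),
    }

    msd_df = migration_stats.msd(nucleus_tracks)
    write_table(msd_df, outdir / "msd.csv")
    pers = migration_stats.persistence_ratio(nucleus_tracks)
    write_table(pers, outdir / "persistence.csv")
    summary["stages"]["migration"] = {
        "msd_final_um2": float(msd_df["msd_um2"].iloc[-1]),
        "persistence_final": float(pers["persistence"].iloc[-1]),
    }

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].hist(events["appear_q"], bins=20, alpha=0.6, label="appear")
    axes[0].hist(events["disappear_q"], bins=20, alpha=0.6, label="disappear")
    axes[0].set_xlabel("q (distance from front)")
    axes[0].set_ylabel("tracks")
    axes[0].legend()
    axes[1].plot(msd_df["lag"], msd_df["msd_um2"])
    axes[1].set_xlabel("lag (frames)")
    axes[1].set_ylabel("MSD (um^2)")
    fig.tight_layout()
    fig.savefig(outdir / "overview.png", dpi=120)
    plt.close(fig)

    summary["timings"] = timings
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline complete: %s", timings)
    return summary
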