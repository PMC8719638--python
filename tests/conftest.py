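"""Shared fixtures: small calibrated scenes with ground truth.

Scenes are generated once per session; tests that need heavier statistics
build their own cohorts.
"""

import dataclasses

import pytest

from polarpunc import DetectionConfig, SceneConfig, detect_stack
from polarpunc.synthetic_scene import simulate_scene


def snr_config(snr: float = 8.0, n_frames: int = 60,
               **overrides) -> SceneConfig:
    """A persistently migrating cell scene at a given peak SNR."""
    base = SceneConfig(image_shape=(n_frames, 128, 280),
                       heading_bias_b=0.25, heading_noise_sd=0.05)
    return dataclasses.replace(
        base, punctum_amplitude=base.amplitude_for_snr(snr), **overrides)


@pytest.fixture(scope="session")
def small_scene():
    """One 60-frame SNR-8 scene with ground truth."""
    cfg = snr_config()
    stack, gt = simulate_scene(cfg, seed=1)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def small_detections(small_scene):
    cfg, stack, gt = small_scene
    masks = [s.mask for s in gt.cell_states]
    det = detect_stack(stack, 0, DetectionConfig(), masks=masks)
    return det


@pytest.fixture(scope="session")
def edta_scene_factory():
    """EDTA-mode scenes: stalled cell, puncta in retrograde flow."""
    cache = {}

    def make(u_px_frame: float, seed: int = 5):
        key = (u_px_frame, seed)
        if key not in cache:
            base = SceneConfig(image_shape=(60, 128, 200),
                               cell_speed_um_min=0.5,
                               heading_noise_sd=0.0)
            cfg = dataclasses.replace(
                base,
                punctum_amplitude=base.amplitude_for_snr(8.0),
                retrograde_speed_um_s=u_px_frame * base.pixel_size_um
                / base.frame_interval_s,
            )
            cache[key] = (cfg,) + simulate_scene(cfg, seed)
        return cache[key]

    return make


def match_detections(det, events_frame, radius_px=2.0):
    """Greedy-by-frame matching of detections to live ground-truth events.

    Returns (tp, n_detections, n_true_frames): a detection is a true
    positive when a live event lies within ``radius_px``.
    """
    tp = 0
    n_true = int(sum(events_frame["death_frame"] - events_frame["birth_frame"]
                     + 1))
    for _, row in det.iterrows():
        alive = events_frame[
            (events_frame["birth_frame"] <= row["frame"])
            & (events_frame["death_frame"] >= row["frame"])]
        if len(alive) == 0:
            continue
        d2 = (alive["x_px"] - row["x_px"]) ** 2 \
            + (alive["y_px"] - row["y_px"]) ** 2
        if d2.min() <= radius_px ** 2:
            tp += 1
    return tp, len(det), n_true
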