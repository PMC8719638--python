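"""Bead detection, selection, Gaussian-volume quantification, profiles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from polarpunc import (BeadSpec, SceneConfig, bead_gaussian_volume,
                       beads_under_cell, box_sum, detect_beads,
                       fraction_positive, gain_loss, integrated_bg_subtracted,
                       per_area)
from polarpunc.bead_enrichment import bead_profile, bead_traces
from polarpunc.cell_frame import CellOutlineSeries
from polarpunc.core import (DegenerateInputError, GeometryError,
                            add_gaussian_spot)
from polarpunc.synthetic_scene import simulate_cell_track, simulate_scene


def bead_frame(x=20.0, y=30.0, a=40.0, sigma=2.0, offset=20.0,
               shape=(64, 64)):
    img = np.full(shape, float(offset))
    add_gaussian_spot(img, x, y, a, sigma, truncate=10)
    return img


class TestDetectBeads:
    def test_localization_within_half_pixel(self):
        rng = np.random.default_rng(0)
        img = bead_frame() + rng.normal(0, 2, (64, 64))
        beads = detect_beads(img)
        assert len(beads) == 1
        assert beads[0].x_px == pytest.approx(20.0, abs=0.5)
        assert beads[0].y_px == pytest.approx(30.0, abs=0.5)

    def test_blank_channel_gives_empty_list(self):
        assert detect_beads(np.zeros((64, 64))) == []

    def test_generator_beads_all_found(self):
        cfg = SceneConfig(image_shape=(3, 96, 160),
                          bead_diameters_nm=(200.0,),
                          bead_density_per_100um2=2.5,
                          birth_rate_lambda=0.0)
        stack, gt = simulate_scene(cfg, seed=4)
        found = detect_beads(stack.frame(0, 2).astype(float))
        assert len(found) == len(gt.beads) > 0


class TestBeadsUnderCell:
    def setup_method(self):
        self.mask = np.zeros((64, 64), dtype=bool)
        self.mask[16:48, 16:48] = True

    def test_central_bead_kept(self):
        b = BeadSpec(0, 32.0, 32.0, 200.0)
        assert beads_under_cell([b], self.mask, 0.16) == [b]

    def test_outside_bead_dropped(self):
        b = BeadSpec(0, 5.0, 5.0, 200.0)
        assert beads_under_cell([b], self.mask, 0.16) == []

    def test_margin_drops_boundary_bead(self):
        # 1 px inside the boundary, margin 3 + radius -> eroded away
        b = BeadSpec(0, 17.0, 32.0, 200.0)
        assert beads_under_cell([b], self.mask, 0.16, margin_px=3) == []


class TestVolumes:
    def test_rendered_bead_volume(self):
        img = bead_frame()
        b = BeadSpec(0, 20.0, 30.0, 200.0)
        vol = bead_gaussian_volume(img, b, window=15)
        assert vol == pytest.approx(2 * np.pi * 40 * 4, rel=0.01)

    def test_background_independence(self):
        b = BeadSpec(0, 20.0, 30.0, 200.0)
        v1 = bead_gaussian_volume(bead_frame(offset=20.0), b, window=15)
        v2 = bead_gaussian_volume(bead_frame(offset=70.0), b, window=15)
        assert v2 == pytest.approx(v1, rel=0.02)

    def test_blank_window_fails(self):
        b = BeadSpec(0, 20.0, 30.0, 200.0)
        assert np.isnan(bead_gaussian_volume(np.zeros((64, 64)), b))

    def test_per_area_arithmetic(self):
        assert per_area(1000.0, 100.0) == pytest.approx(1000 / (np.pi * 1e4))
        assert per_area(10.0, 100.0) / per_area(10.0, 200.0) \
            == pytest.approx(4.0)


class TestFractionPositive:
    def test_all_strong_beads(self):
        frames = [bead_frame(a=60.0)]
        beads = [BeadSpec(0, 20.0, 30.0, 200.0)]
        frac, flags = fraction_positive(frames, beads)
        assert frac == 1.0 and flags == [True]

    def test_no_signal(self):
        rng = np.random.default_rng(1)
        frames = [rng.normal(20, 2, (64, 64))]
        beads = [BeadSpec(i, 15.0 + 8 * i, 30.0, 200.0) for i in range(4)]
        frac, _ = fraction_positive(frames, beads)
        assert frac == 0.0

    def test_half_positive(self):
        rng = np.random.default_rng(2)
        img = np.full((64, 64), 20.0)
        beads = []
        for i in range(10):
            x, y = 8.0 + 6 * (i % 8), 16.0 + 24 * (i // 8)
            if i % 2 == 0:
                add_gaussian_spot(img, x, y, 60.0, 1.5)
            beads.append(BeadSpec(i, x, y, 200.0))
        img = img + rng.normal(0, 2, img.shape)
        frac, flags = fraction_positive([img], beads)
        assert frac == pytest.approx(0.5, abs=0.2)
        assert flags[0] and not flags[1]


class TestIntegratedAndBox:
    def test_uniform_image_integrates_to_zero(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:8] = True
        assert integrated_bg_subtracted(np.full((16, 16), 7.0), mask) == 0.0

    def test_known_offset(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:8] = True
        img = np.full((16, 16), 3.0)
        img[mask] += 5.0
        assert integrated_bg_subtracted(img, mask) \
            == pytest.approx(mask.sum() * 5.0)

    def test_agrees_with_gaussian_volume(self):
        img = bead_frame(a=50.0, sigma=2.0, offset=10.0)
        b = BeadSpec(0, 20.0, 30.0, 200.0)
        mask = np.zeros_like(img, dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(xx - 20) ** 2 + (yy - 30) ** 2 <= 8 ** 2] = True
        v_sum = integrated_bg_subtracted(img, mask)
        v_fit = bead_gaussian_volume(img, b, window=15)
        assert v_sum == pytest.approx(v_fit, rel=0.10)

    def test_box_sums(self):
        b = BeadSpec(0, 8.0, 8.0, 100.0)
        assert box_sum(np.zeros((17, 17)), b, 5) == 0.0
        assert box_sum(np.ones((17, 17)), b, 5) == 25.0
        with pytest.raises(GeometryError):
            box_sum(np.ones((17, 17)), BeadSpec(1, 1.0, 1.0, 100.0), 9)


def front_gated_scene():
    # beads laid along the migration path so the cell passes fully over them
    from polarpunc.synthetic_scene import render
    base = SceneConfig(image_shape=(200, 128, 440),
                       bead_diameters_nm=(200.0,),
                       bead_signal_rule="front_gated",
                       birth_rate_lambda=0.0,
                       heading_noise_sd=0.0)
    cfg = dataclasses.replace(base,
                              punctum_amplitude=base.amplitude_for_snr(8.0))
    states = simulate_cell_track(cfg, seed=11)
    beads = [BeadSpec(i, 116.0 + 16 * i, 60.0 if i % 2 else 68.0, 200.0)
             for i in range(7)]
    stack, gt = render(states, [], beads, cfg, seed=12, second_events=[])
    return cfg, stack, gt


@pytest.fixture(scope="module")
def front_gated():
    return front_gated_scene()


class TestProfiles:
    def test_single_bead_constant_signal(self):
        rows = []
        for t, q in enumerate(np.linspace(0.05, 0.95, 10)):
            rows.append((0, t, q, 50.0, np.nan, True))
        traces = pd.DataFrame(rows, columns=("bead_id", "frame", "q",
                                             "box_sum", "volume",
                                             "under_cell"))
        profile, _ = bead_profile(traces)
        np.testing.assert_allclose(profile["mean_norm_signal"], 1.0)

    def test_two_identical_beads_average_to_one_trace(self):
        rows = []
        for bead in (0, 1):
            for t, (q, v) in enumerate(zip([0.1, 0.3, 0.5], [10, 40, 20])):
                rows.append((bead, t, q, float(v), np.nan, True))
        traces = pd.DataFrame(rows, columns=("bead_id", "frame", "q",
                                             "box_sum", "volume",
                                             "under_cell"))
        profile, _ = bead_profile(traces)
        np.testing.assert_allclose(profile["mean_norm_signal"],
                                   [0.25, 1.0, 0.5])

    def test_degenerate_zero_trace_rejected(self):
        rows = [(0, t, 0.1 * t, 0.0, np.nan, True) for t in range(5)]
        traces = pd.DataFrame(rows, columns=("bead_id", "frame", "q",
                                             "box_sum", "volume",
                                             "under_cell"))
        with pytest.raises(DegenerateInputError):
            bead_profile(traces)

    @staticmethod
    def full_transit_traces(stack, gt):
        outline = CellOutlineSeries.from_cell_states(gt.cell_states)
        traces = bead_traces(stack, 0, gt.beads, outline)
        under = traces[traces["under_cell"]]
        span = under.groupby("bead_id")["q"].agg(["min", "max"])
        full = span[(span["min"] <= 0.15) & (span["max"] >= 0.85)].index
        return traces[traces["bead_id"].isin(full) & traces["under_cell"]]

    def test_front_gated_profile_shape(self, front_gated):
        # only beads the cell passed fully over are profiled, as partial
        # transits normalize to their own noise floor
        cfg, stack, gt = front_gated
        use = self.full_transit_traces(stack, gt)
        assert use["bead_id"].nunique() >= 3
        profile, points = bead_profile(use, value_col="box_sum_bg")
        prof = profile.set_index("q_bin")["mean_norm_signal"]
        assert prof.idxmax() in (0.2, 0.3, 0.4)
        rear = prof[prof.index >= 0.7]
        assert (rear <= 0.05).all()
        assert points["kde_weight"].notna().all()

    def test_gain_loss_classification(self, front_gated):
        cfg, stack, gt = front_gated
        use = self.full_transit_traces(stack, gt)
        noise_floor = 3 * cfg.noise_sd() * 9 * np.sqrt(2)  # box-sum diffs
        correct = total = 0
        for _, tr in use.groupby("bead_id"):
            # difference over ~8 s intervals: per-second increments sit
            # below the box-sum shot noise at this imaging rate
            tr = tr.iloc[::8]
            if len(tr) < 2:
                continue
            gl = gain_loss(tr, value_col="box_sum_bg",
                           noise_floor=noise_floor)
            for _, r in gl.iterrows():
                if r["q_mid"] < 0.3:
                    total += 1
                    correct += r["label"] == "gain"
                elif r["q_mid"] > 0.4:
                    total += 1
                    correct += r["label"] == "loss"
        assert total > 10
        assert correct / total >= 0.8

    def test_monotone_trace_all_gains(self):
        tr = pd.DataFrame({"frame": range(5), "q": np.linspace(0.1, 0.5, 5),
                           "box_sum": [1.0, 2.0, 4.0, 8.0, 16.0]})
        gl = gain_loss(tr)
        assert (gl["label"] == "gain").all()

    def test_constant_trace_yields_nothing(self):
        tr = pd.DataFrame({"frame": range(5), "q": np.linspace(0.1, 0.5, 5),
                           "box_sum": [3.0] * 5})
        assert len(gain_loss(tr, noise_floor=0.5)) == 0


class TestEndToEndCurvature:
    def test_per_area_constant_across_diameters(self):
        # the surface-area normalisation makes the per-area signal equal for
        # 100 and 200 nm beads when the generator deposits signal per area
        base = SceneConfig(image_shape=(40, 128, 280),
                           bead_diameters_nm=(100.0, 200.0),
                           bead_density_per_100um2=1.2,
                           bead_signal_rule="per_area_constant",
                           birth_rate_lambda=0.0,
                           heading_noise_sd=0.0)
        stack, gt = simulate_scene(base, seed=21)
        per_d = {100.0: [], 200.0: []}
        for b in gt.beads:
            best, vol = -np.inf, np.nan
            for t in range(stack.n_frames):
                from polarpunc.synthetic_scene import relative_q
                q = relative_q((b.x_px, b.y_px), gt.cell_states[t])
                if 0.1 <= q <= 0.9:
                    frame = stack.frame(t, 0).astype(float)
                    s = box_sum(frame, b, 9)
                    if s > best:
                        best = s
                        vol = bead_gaussian_volume(frame, b, 11)
            if np.isfinite(vol):
                per_d[b.diameter_nm].append(per_area(vol, b.diameter_nm))
        m100 = np.mean(per_d[100.0])
        m200 = np.mean(per_d[200.0])
        assert m100 / m200 == pytest.approx(1.0, abs=0.1)
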