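"""Generator: cell kinematics, event-model calibration, beads, rendering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from polarpunc import SceneConfig, bead_signal, place_beads
from polarpunc.core import (CalibrationError, PackingError,
                            SceneTruncationError, add_gaussian_spot)
from polarpunc.synthetic_scene import (
    DEFAULT_BIRTH_MU_RAW,
    DEFAULT_DEATH_MU_RAW,
    DEFAULT_DEATH_SD_RAW,
    GroundTruth,
    _realized_stats,
    calibrate_event_model,
    closed_form_raw_parameters,
    draw_event_pairs,
    render,
    render_clean,
    simulate_cell_track,
    simulate_scene,
    spawn_puncta,
)


# ---------------------------------------------------------------------------
# cell track
# ---------------------------------------------------------------------------

class TestCellTrack:
    def test_zero_speed_is_a_fixed_point(self):
        cfg = SceneConfig(image_shape=(10, 96, 160), cell_speed_um_min=0.0)
        states = simulate_cell_track(cfg, seed=7)
        c0 = np.asarray(states[0].centroid)
        for s in states:
            assert np.allclose(s.centroid, c0)

    def test_clamped_heading_straight_run(self):
        # noiseless, heading locked on the x axis: 2 px/frame for 10 frames
        # nets exactly (20, 0) px of displacement over 10 steps
        v_um_min = 2.0 * 0.16 * 60  # 2 px/frame at defaults
        cfg = SceneConfig(image_shape=(11, 96, 200),
                          cell_speed_um_min=v_um_min,
                          heading_noise_sd=0.0, heading_bias_b=5.0)
        states = simulate_cell_track(cfg, seed=0)
        d = np.asarray(states[10].centroid) - np.asarray(states[0].centroid)
        assert np.allclose(d, (20.0, 0.0), atol=1e-9)

    def test_unbiased_heading_walk_is_isotropic(self):
        # Monte-Carlo oracle on the heading recursion: with b = 0 the mean
        # per-step |dx| and |dy| converge to the same value
        cfg = SceneConfig(image_shape=(10_000, 4096, 4096),
                          heading_noise_sd=0.3, heading_bias_b=0.0,
                          initial_centroid_px=(2048.0, 2048.0))
        states = simulate_cell_track(cfg, seed=11, compute_masks=False)
        pos = np.array([s.centroid for s in states])
        steps = np.diff(pos, axis=0)
        ratio = np.mean(np.abs(steps[:, 0])) / np.mean(np.abs(steps[:, 1]))
        assert abs(ratio - 1.0) < 0.05

    def test_leaving_frame_signals_truncation(self):
        cfg = SceneConfig(image_shape=(400, 96, 160),
                          heading_noise_sd=0.0, heading_bias_b=1.0)
        with pytest.raises(SceneTruncationError) as exc:
            simulate_cell_track(cfg, seed=0)
        assert 0 < exc.value.last_valid_frame < 400

    def test_anchor_geometry(self):
        cfg = SceneConfig(image_shape=(5, 128, 256), heading_noise_sd=0.1)
        states = simulate_cell_track(cfg, seed=3)
        for s in states:
            np.testing.assert_allclose(
                s.length_px, cfg.length_px, rtol=1e-9)
            assert s.mask[int(round(s.centroid[1])),
                          int(round(s.centroid[0]))]


# ---------------------------------------------------------------------------
# event model
# ---------------------------------------------------------------------------

class TestEventModel:
    def test_closed_form_initialisation(self):
        # no-truncation limit: mu equal to the targets and
        # sigma_d = (0.5 - 0.374) / PHI^-1(0.84) = 0.126
        mu_b, mu_d, sd = closed_form_raw_parameters(0.198, 0.374, 0.841345)
        assert mu_b == pytest.approx(0.198)
        assert mu_d == pytest.approx(0.374)
        assert sd == pytest.approx(0.126, abs=2e-3)

    def test_calibration_reproduces_shipped_defaults(self):
        mu_b, mu_d, sd = calibrate_event_model(n_mc=500_000)
        assert mu_b == pytest.approx(DEFAULT_BIRTH_MU_RAW, abs=1e-3)
        assert mu_d == pytest.approx(DEFAULT_DEATH_MU_RAW, abs=5e-3)
        assert sd == pytest.approx(DEFAULT_DEATH_SD_RAW, abs=5e-3)

    def test_calibration_monte_carlo_self_consistency(self):
        # an independent resampling of 10^6 pairs reproduces all three
        # target statistics
        rng = np.random.default_rng(2024)
        zb = rng.standard_normal(1_000_000)
        zd = rng.standard_normal(1_000_000)
        got = _realized_stats(DEFAULT_BIRTH_MU_RAW, DEFAULT_DEATH_MU_RAW,
                              DEFAULT_DEATH_SD_RAW, 0.05, 0.03, zb, zd)
        assert got[0] == pytest.approx(0.198, abs=2e-3)
        assert got[1] == pytest.approx(0.374, abs=2e-3)
        assert got[2] == pytest.approx(0.84, abs=2e-3)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_event_model(target_birth_mean=1.5)

    def test_infeasible_targets_raise_calibration_error(self):
        # the acceptance gap delta = 0.05 makes the default targets
        # unattainable for this family (documented limitation)
        with pytest.raises(CalibrationError):
            calibrate_event_model(delta=0.05, n_mc=200_000)

    def test_drawn_pairs_respect_constraints(self):
        cfg = SceneConfig()
        rng = np.random.default_rng(5)
        pairs = draw_event_pairs(20_000, cfg, rng)
        assert np.all(pairs[:, 0] >= 0) and np.all(pairs[:, 1] <= 1)
        assert np.all(pairs[:, 1] >= pairs[:, 0] + cfg.min_gap_delta - 1e-12)


# ---------------------------------------------------------------------------
# punctum events
# ---------------------------------------------------------------------------

class TestSpawn:
    def test_zero_rate_gives_no_events(self):
        cfg = SceneConfig(image_shape=(10, 128, 200), birth_rate_lambda=0.0)
        states = simulate_cell_track(cfg, seed=1)
        assert spawn_puncta(states, cfg, seed=2) == []

    def test_poisson_event_count(self):
        # 20 cells x 300 frames at lambda = 0.5: total count within
        # 3*sqrt(3000) of 3000
        cfg = SceneConfig(image_shape=(300, 512, 1024),
                          heading_bias_b=0.25,
                          initial_centroid_px=(80.0, 256.0))
        total = 0
        for seed in range(20):
            states = simulate_cell_track(cfg, seed, compute_masks=False)
            total += len(spawn_puncta(states, cfg, seed + 1000))
        expect = 20 * 300 * cfg.birth_rate_lambda
        assert abs(total - expect) <= 3 * np.sqrt(expect)

    def test_substrate_fixed_positions_are_constant(self):
        cfg = SceneConfig(image_shape=(40, 128, 256), heading_bias_b=0.25)
        states = simulate_cell_track(cfg, seed=4)
        events = spawn_puncta(states, cfg, seed=5)
        assert len(events) > 0
        for e in events:
            pos = e.positions(states, retrograde_px_frame=0.0)
            assert np.ptp(pos, axis=0).max() == 0.0

    def test_birth_death_ordering(self):
        cfg = SceneConfig(image_shape=(40, 128, 256), heading_bias_b=0.25)
        states = simulate_cell_track(cfg, seed=4)
        for e in spawn_puncta(states, cfg, seed=5):
            assert e.death_frame >= e.birth_frame
            assert 0 <= e.birth_q <= e.death_q <= 1

    def test_realized_birth_statistics_match_calibration(self):
        # ground-truth birth/death means across >= 10^4 events match the
        # calibrated targets within 3 standard errors
        cfg = SceneConfig(image_shape=(300, 512, 1024),
                          heading_bias_b=0.25,
                          initial_centroid_px=(80.0, 256.0))
        qb, qd = [], []
        for seed in range(40):
            states = simulate_cell_track(cfg, seed, compute_masks=False)
            for e in spawn_puncta(states, cfg, seed + 999):
                qb.append(e.birth_q)
                qd.append(e.death_q)
        qb, qd = np.asarray(qb), np.asarray(qd)
        assert len(qb) > 4000
        assert abs(qb.mean() - 0.198) < 3 * qb.std() / np.sqrt(len(qb)) + 1e-3
        assert abs(qd.mean() - 0.374) < 3 * qd.std() / np.sqrt(len(qd)) + 1e-3


# ---------------------------------------------------------------------------
# beads
# ---------------------------------------------------------------------------

class TestBeads:
    def test_per_area_constant_total_scales_with_d_squared(self):
        s100 = bead_signal(0.3, 100, "per_area_constant")
        s200 = bead_signal(0.3, 200, "per_area_constant")
        assert s200 / s100 == pytest.approx(4.0)

    def test_front_gate_vanishes_at_rear(self):
        cfg = SceneConfig()
        assert bead_signal(0.9, 200, "front_gated", cfg) \
            < 0.05 * cfg.bead_front_smax

    def test_front_gate_peaks_in_front_band(self):
        qs = np.linspace(0, 1, 501)
        vals = [bead_signal(q, 200, "front_gated") for q in qs]
        assert 0.2 <= qs[int(np.argmax(vals))] <= 0.4

    def test_signal_zero_when_not_under_cell(self):
        assert bead_signal(-0.1, 100, "per_area_constant") == 0.0
        assert bead_signal(1.2, 100, "front_gated") == 0.0

    def test_minimum_separation_and_packing_failure(self):
        cfg = SceneConfig(image_shape=(5, 64, 64), bead_diameters_nm=(200,),
                          bead_density_per_100um2=3.0)
        beads = place_beads(cfg, seed=1)
        pos = np.array([[b.x_px, b.y_px] for b in beads])
        if len(pos) > 1:
            d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 4 * cfg.psf_sigma_px
        dense = dataclasses.replace(cfg, bead_density_per_100um2=3000.0)
        with pytest.raises(PackingError):
            place_beads(dense, seed=1)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

class TestRender:
    def test_noise_free_render_matches_template(self):
        # with no events and no flatfield the clean rendering is exactly the
        # smoothed cytoplasm template, and the camera rendering differs only
        # by quantisation once the shot noise is driven to zero
        cfg = SceneConfig(image_shape=(3, 96, 160), birth_rate_lambda=0.0,
                          read_noise_sd=0.0, photon_gain=1e7,
                          flatfield_amp=0.0)
        states = simulate_cell_track(cfg, seed=1)
        from scipy import ndimage
        template = np.stack([ndimage.gaussian_filter(
            s.mask.astype(float) * cfg.cytoplasm_level, 2.0) for s in states])
        clean = render_clean(states, [], [], cfg)
        np.testing.assert_array_equal(clean[:, 3], template)
        stack, _ = render(states, [], [], cfg, seed=2, second_events=[])
        diff = stack.data[:, 3].astype(float) - np.rint(template)
        assert np.abs(diff).max() <= 1.0
        assert np.mean(diff != 0) < 0.02

    def test_spot_volume_summation_oracle(self):
        # direct summation: a rendered Gaussian A=100, sigma=2 integrates to
        # 2*pi*100*4 over a 41x41 window within 1%
        img = np.zeros((41, 41))
        add_gaussian_spot(img, 20.0, 20.0, 100.0, 2.0, truncate=12)
        assert img.sum() == pytest.approx(2 * np.pi * 100 * 4, rel=0.01)

    def test_poisson_noise_variance(self):
        cfg = SceneConfig(image_shape=(1, 96, 160), birth_rate_lambda=0.0,
                          read_noise_sd=0.0, photon_gain=2.0)
        states = simulate_cell_track(cfg, seed=1)
        stack, _ = render(states, [], [], cfg, seed=3, second_events=[])
        mask = states[0].mask
        core = ndi_erode(mask, 8)
        vals = stack.data[0, 3].astype(float)[core]
        m = vals.mean()
        assert vals.var() == pytest.approx(m / cfg.photon_gain, rel=0.10)

    def test_render_reproducible_bit_for_bit(self):
        cfg = SceneConfig(image_shape=(4, 96, 160), heading_bias_b=0.25)
        s1, _ = simulate_scene(cfg, seed=9)
        s2, _ = simulate_scene(cfg, seed=9)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_second_marker_never_colocates(self, small_scene):
        _, _, gt = small_scene
        main = np.array([[e.x_px, e.y_px] for e in gt.events])
        for e in gt.second_events:
            d = np.sqrt(((main - [e.x_px, e.y_px]) ** 2).sum(axis=1)).min()
            assert d >= 3.0

    def test_ground_truth_csv_roundtrip(self, tmp_path, small_scene):
        _, _, gt = small_scene
        gt.write(tmp_path)
        back = GroundTruth.read_events(tmp_path / "ground_truth_events.csv")
        pd.testing.assert_frame_equal(back, gt.events_frame(),
                                      check_exact=True)


def ndi_erode(mask, n):
    from scipy import ndimage
    return ndimage.binary_erosion(mask, iterations=n)
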