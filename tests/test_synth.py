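"""Ground-truth generator: kinematics, rendering, cell sheets, pulses."""

import numpy as np
import pandas as pd
import pytest

from myoflow import synth
from myoflow.errors import ConfigurationError
from myoflow.pulses import series_from_table
from myoflow.synth import (CellSheetSpec, DotPopulationSpec, FixedDirection,
                           QuadrantMixture, SceneConfig, VonMisesDirection)


def step_vectors(tracks: pd.DataFrame) -> pd.DataFrame:
    return tracks.groupby("track_id")[["x_um", "y_um"]].diff().dropna()


class TestTrackKinematics:
    def test_stationary_dots_never_move(self, small_scene):
        tracks = synth.generate_tracks(
            small_scene, DotPopulationSpec(n_dots=5, speed=0.0))
        steps = step_vectors(tracks)
        assert np.all(steps.to_numpy() == 0.0)

    def test_fixed_direction_step_length_is_speed_times_interval(self):
        # 2.44 µm/min at 6 s -> 0.244 µm per step, straight Up
        scene = SceneConfig(image_shape=(256, 256), n_frames=6, seed=3)
        tracks = synth.generate_tracks(
            scene, DotPopulationSpec(n_dots=8, speed=2.44,
                                     direction_model=FixedDirection(90.0)))
        steps = step_vectors(tracks)
        np.testing.assert_allclose(steps["x_um"], 0.0, atol=1e-12)
        np.testing.assert_allclose(steps["y_um"], 0.244, atol=1e-12)

    def test_default_scene_matches_imaging_regime(self):
        scene = SceneConfig()
        assert scene.frame_interval == 6.0
        assert 300.0 <= scene.duration_s <= 600.0

    def test_mean_speed_converges_to_requested(self):
        scene = SceneConfig(image_shape=(512, 512), n_frames=21, seed=5)
        dots = DotPopulationSpec(n_dots=120, speed=2.0,
                                 direction_model=VonMisesDirection(270, 2.0))
        tracks = synth.generate_tracks(scene, dots)
        ok = tracks[~tracks["reflected"]]
        lengths = step_vectors(ok)
        speeds = np.hypot(lengths.x_um, lengths.y_um) / 6.0 * 60.0
        sem = speeds.std(ddof=1) / np.sqrt(len(speeds))
        assert abs(speeds.mean() - 2.0) < max(3 * sem, 1e-9)

    def test_quadrant_mixture_retro_fraction_converges(self, rng):
        n = 4000
        angles = QuadrantMixture(0.77).sample(n, rng)
        in_down = ((angles >= 225) & (angles < 315)).mean()
        # 3-sigma binomial interval around p_retro
        assert abs(in_down - 0.77) < 3 * np.sqrt(0.77 * 0.23 / n)

    def test_reflection_flagged_at_boundary(self):
        scene = SceneConfig(image_shape=(40, 40), n_frames=30, seed=2)
        tracks = synth.generate_tracks(
            scene, DotPopulationSpec(n_dots=4, speed=6.0,
                                     direction_model=FixedDirection(90.0)))
        assert tracks["reflected"].any()
        w, h = scene.extent_um
        assert tracks["x_um"].between(0, w).all()
        assert tracks["y_um"].between(0, h).all()

    def test_min_separation_respected_and_infeasible_raises(self):
        scene = SceneConfig(image_shape=(100, 100), n_frames=2, seed=1)
        tracks = synth.generate_tracks(
            scene, DotPopulationSpec(n_dots=12, speed=0.0,
                                     min_separation=2.0))
        p = tracks[tracks.frame == 0][["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(p[:, None] - p[None, :], axis=2)
        assert d[~np.eye(len(p), dtype=bool)].min() >= 2.0
        with pytest.raises(ConfigurationError):
            synth.generate_tracks(
                scene, DotPopulationSpec(n_dots=500, speed=0.0,
                                         min_separation=2.0))

    def test_invalid_scene_rejected(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(image_shape=(0, 100))
        with pytest.raises(ConfigurationError):
            SceneConfig(pixel_size=-0.1)
        with pytest.raises(ConfigurationError):
            SceneConfig(n_frames=1)


class TestDeterminism:
    def test_identical_seeds_bit_identical_different_seeds_differ(self):
        def bundle(seed):
            scene = SceneConfig(image_shape=(64, 64), n_frames=5, seed=seed)
            dots = DotPopulationSpec(n_dots=6)
            cells = CellSheetSpec(n_cells=4, mean_cell_area=2.0)
            tracks = synth.generate_tracks(scene, dots)
            movie = synth.render_movie(tracks, scene)
            labels, _ = synth.generate_cell_sheet(cells, scene)
            pulse = synth.generate_pulse_series(cells, scene)
            return tracks, movie, labels, pulse

        a1, a2, b = bundle(11), bundle(11), bundle(12)
        pd.testing.assert_frame_equal(a1[0], a2[0])
        assert np.array_equal(a1[1], a2[1])
        assert np.array_equal(a1[2], a2[2])
        pd.testing.assert_frame_equal(a1[3], a2[3])
        assert not a1[0][["x_um", "y_um"]].equals(b[0][["x_um", "y_um"]])
        assert not np.array_equal(a1[1], b[1])


class TestRendering:
    def test_empty_track_table_gives_background_plus_noise_only(self):
        scene = SceneConfig(image_shape=(48, 48), n_frames=3, seed=4,
                            background_level=100.0, noise_sd=3.0)
        movie = synth.render_movie(pd.DataFrame(columns=synth.TRACK_COLUMNS),
                                   scene)
        assert movie.shape == (3, 48, 48)
        assert abs(movie.mean() - 100.0) < 1.0
        assert movie.std() < 4.0

    def test_single_spot_integrated_intensity_matches_gaussian_integral(self):
        scene = SceneConfig(image_shape=(64, 64), n_frames=2, seed=0,
                            background_level=10.0, noise_sd=0.0)
        fwhm, amp = 0.5, 300.0
        tracks = pd.DataFrame({
            "track_id": [0, 0], "frame": [0, 1],
            "x_um": [3.2, 3.2], "y_um": [3.2, 3.2],
            "diameter_um": fwhm, "intensity": amp,
            "cell_id": 0, "chamber_id": 0, "reflected": False})
        movie = synth.render_movie(tracks, scene).astype(float)
        sigma_px = fwhm / scene.pixel_size / (2 * np.sqrt(2 * np.log(2)))
        expected = amp * 2 * np.pi * sigma_px ** 2
        measured = (movie[0] - 10.0).sum()
        assert abs(measured - expected) / expected < 0.01

    def test_single_spot_centroid_matches_truth_within_tenth_pixel(self):
        scene = SceneConfig(image_shape=(64, 64), n_frames=2, seed=0,
                            background_level=10.0, noise_sd=0.0)
        x0, y0 = 3.137, 2.819
        tracks = pd.DataFrame({
            "track_id": [0, 0], "frame": [0, 1],
            "x_um": x0, "y_um": y0, "diameter_um": 0.4,
            "intensity": 200.0, "cell_id": 0, "chamber_id": 0,
            "reflected": False})
        frame = synth.render_movie(tracks, scene).astype(float)[0] - 10.0
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        r_cm = (rr * frame).sum() / frame.sum()
        c_cm = (cc * frame).sum() / frame.sum()
        x_cm = c_cm * scene.pixel_size
        y_cm = (64 - 1 - r_cm) * scene.pixel_size
        assert np.hypot(x_cm - x0, y_cm - y0) / scene.pixel_size < 0.1

    def test_sub_resolution_dot_warns(self):
        scene = SceneConfig(image_shape=(32, 32), n_frames=2, seed=0)
        tracks = pd.DataFrame({
            "track_id": [0, 0], "frame": [0, 1], "x_um": 1.5, "y_um": 1.5,
            "diameter_um": 0.15, "intensity": 100.0, "cell_id": 0,
            "chamber_id": 0, "reflected": False})
        with pytest.warns(UserWarning, match="sub-resolution"):
            synth.render_movie(tracks, scene)


class TestCellSheet:
    def test_label_masks_tile_without_overlap(self):
        scene = SceneConfig(image_shape=(80, 80), n_frames=3, seed=9)
        cells = CellSheetSpec(n_cells=9, mean_cell_area=6.0)
        labels, truth = synth.generate_cell_sheet(cells, scene)
        assert labels.shape == (3, 80, 80)
        assert labels.min() >= 1  # every pixel belongs to exactly one cell
        assert set(np.unique(labels)) == set(range(1, 10))
        assert len(truth) == 9 * 3

    def test_translation_moves_centroids_up(self):
        scene = SceneConfig(image_shape=(80, 80), n_frames=4, seed=9)
        cells = CellSheetSpec(n_cells=9, mean_cell_area=6.0,
                              tissue_translation_speed=1.0,
                              translation_direction="Up")
        _, truth = synth.generate_cell_sheet(cells, scene)
        per_frame = truth.groupby("frame")["y_um"].mean()
        dy = np.diff(per_frame.to_numpy())
        np.testing.assert_allclose(dy, 1.0 * 6 / 60, atol=1e-9)


class TestPulseSeries:
    def test_300s_movie_gives_51_point_series(self):
        scene = SceneConfig(n_frames=51, seed=1)
        assert scene.duration_s == 300.0
        table = synth.generate_pulse_series(CellSheetSpec(n_cells=3), scene)
        assert (table.groupby("cell_id").size() == 51).all()

    def test_zero_lag_noiseless_rates_perfectly_correlated(self):
        scene = SceneConfig(n_frames=51, seed=2)
        cells = CellSheetSpec(n_cells=1, intensity_to_area_lag=0,
                              pulse_noise_sd=0.0)
        s = series_from_table(synth.generate_pulse_series(cells, scene))[0]
        ir = np.diff(s.intensity)
        ar = -np.diff(s.area)
        r = np.corrcoef(ir, ar)[0, 1]
        assert r > 1 - 1e-9

    def test_one_frame_lag_brute_force_peak_at_plus_6s(self):
        # independent oracle: plain-numpy correlation at every offset
        scene = SceneConfig(n_frames=51, seed=3)
        cells = CellSheetSpec(n_cells=1, intensity_to_area_lag=1,
                              pulse_noise_sd=0.0)
        s = series_from_table(synth.generate_pulse_series(cells, scene))[0]
        x = np.diff(s.intensity)
        y = -np.diff(s.area)
        best, best_r = None, -2
        for k in range(-10, 11):
            a, b = (x[:len(x) - k], y[k:]) if k >= 0 else (x[-k:], y[:k])
            r = np.corrcoef(a, b)[0, 1]
            if r > best_r:
                best, best_r = k, r
        assert best == 1  # one frame = +6 s

    def test_area_stays_positive(self):
        scene = SceneConfig(n_frames=51, seed=4)
        cells = CellSheetSpec(n_cells=10, pulse_amplitude=0.8,
                              pulse_noise_sd=0.3)
        table = synth.generate_pulse_series(cells, scene)
        assert (table["area_um2"] > 0).all()

    def test_lag_longer_than_movie_rejected(self):
        scene = SceneConfig(n_frames=20, seed=0)
        with pytest.raises(ConfigurationError):
            synth.generate_pulse_series(
                CellSheetSpec(intensity_to_area_lag=20), scene)


class TestAngularEvents:
    def test_down_chambers_are_mirrored(self, rng):
        ev = synth.generate_angular_events(
            4, 50, FixedDirection(270.0), rng,
            rotation_directions=["Up", "Down", "Up", "Down"])
        up = ev[ev.rotation_direction == "Up"]
        down = ev[ev.rotation_direction == "Down"]
        assert np.allclose(up["angle_deg"], 270.0)
        assert np.allclose(down["angle_deg"], 90.0)
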