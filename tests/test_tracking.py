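"""Soma extraction, geodesic lengths, tracking, kymographs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk

from wavetrack.errors import (DisconnectionError, GeometryError, SeedError)
from wavetrack.imageproc import CalibratedStack
from wavetrack.tracking import (SeedAnnotation, build_kymograph, extract_soma,
                                geodesic_distance_map, geodesic_length,
                                track_trajectory)


from helpers import networkx_geodesic as _networkx_geodesic
from helpers import random_connected_mask as _random_connected_mask


class TestExtractSoma:
    def test_disc_area_and_centroid(self):
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), 15)
        img[rr, cc] = 100.0
        mask, centroid = extract_soma(img, (32, 32), threshold=50.0)
        assert abs(mask.sum() - np.pi * 15**2) / (np.pi * 15**2) < 0.02
        assert np.hypot(*(centroid - 32)) < 0.5

    def test_seed_on_background_raises(self):
        img = np.zeros((32, 32))
        img[5, 5] = 10
        with pytest.raises(SeedError, match="(2, 2)"):
            extract_soma(img, (2, 2), threshold=5.0)

    def test_max_radius_bounds_growth(self):
        img = np.full((64, 64), 100.0)
        mask, _ = extract_soma(img, (32, 32), threshold=50.0, max_radius_px=10)
        assert mask.sum() <= np.pi * 10.5**2


class TestGeodesicLength:
    def test_straight_segment(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 3:13] = True
        assert geodesic_length(mask, (8, 3), (8, 12), 0.5) == pytest.approx(9 * 0.5)

    def test_diagonal_weight(self):
        mask = np.eye(9, dtype=bool)
        d = geodesic_length(mask, (0, 0), (8, 8), 1.0)
        assert d == pytest.approx(8 * np.sqrt(2))

    def test_background_and_disconnection_errors(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2, 2:6] = True
        mask[10, 2:6] = True
        with pytest.raises(SeedError):
            geodesic_length(mask, (0, 0), (2, 3), 1.0)
        with pytest.raises(DisconnectionError):
            geodesic_length(mask, (2, 2), (10, 3), 1.0)

    def test_matches_dijkstra_oracle_on_random_masks(self, rng):
        for _ in range(100):
            mask = _random_connected_mask(rng)
            ys, xs = np.nonzero(mask)
            i, j = rng.integers(len(ys), size=2)
            p1, p2 = (ys[i], xs[i]), (ys[j], xs[j])
            mine = geodesic_length(mask, p1, p2, 1.0)
            ref = _networkx_geodesic(mask, p1, p2)
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_symmetry(self, rng):
        mask = _random_connected_mask(rng)
        ys, xs = np.nonzero(mask)
        i, j = rng.integers(len(ys), size=2)
        d12 = geodesic_length(mask, (ys[i], xs[i]), (ys[j], xs[j]), 1.0)
        d21 = geodesic_length(mask, (ys[j], xs[j]), (ys[i], xs[i]), 1.0)
        assert d12 == d21

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        mask = _random_connected_mask(rng, n_grow=200)
        ys, xs = np.nonzero(mask)
        i, j, k = rng.integers(len(ys), size=3)
        a, b, c = (ys[i], xs[i]), (ys[j], xs[j]), (ys[k], xs[k])
        dab = geodesic_length(mask, a, b, 1.0)
        dac = geodesic_length(mask, a, c, 1.0)
        dcb = geodesic_length(mask, c, b, 1.0)
        assert dab <= dac + dcb + 1e-9

    def test_distance_map_source_on_background(self):
        with pytest.raises(SeedError):
            geodesic_distance_map(np.zeros((8, 8), dtype=bool), (4, 4))


class TestTrackTrajectory:
    def test_static_scene_constant(self):
        """A frozen neurite gives constant positions and length."""
        from wavetrack import imageproc, simgen

        params = simgen.movie_preset(
            "paper-regime-20x", rng_seed=9, duration_min=18.0,
            frame_interval_s=120.0, image_shape=(128, 280),
            initial_length_um=70.0, wave_rate_per_h=1e-9,
            growth_speed_free_um_min=1e-6, read_noise_sd=2.0)
        stack, truth = simgen.simulate_movie(params)
        maps = [imageproc.make_feature_map(f) for f in stack.frames]
        seeds = SeedAnnotation(
            soma_point=truth.seeds["soma"], hillock_point=truth.seeds["hillock"],
            edge_point=truth.seeds["edge"])
        traj = track_trajectory(stack, maps, seeds)
        px = params.pixel_size_um
        assert np.nanmax(np.abs(traj.length_um - np.nanmedian(traj.length_um))) <= 1.5 * px
        assert np.all(np.abs(traj.edge_rc - traj.edge_rc[0]) <= 1.5)
        assert np.all(np.abs(traj.soma_rc - traj.soma_rc[0]) <= 1.0)

    def test_waveless_movie_flags_every_frame(self, small_movie):
        from wavetrack import imageproc, simgen

        params = simgen.movie_preset(
            "paper-regime-20x", rng_seed=21, duration_min=20.0,
            image_shape=(128, 280), initial_length_um=70.0, wave_rate_per_h=1e-9)
        stack, truth = simgen.simulate_movie(params)
        maps = [imageproc.make_feature_map(f) for f in stack.frames]
        seeds = SeedAnnotation(
            soma_point=truth.seeds["soma"], hillock_point=truth.seeds["hillock"],
            edge_point=truth.seeds["edge"])
        traj = track_trajectory(stack, maps, seeds)
        assert not traj.wave_present.any()

    def test_wave_position_tracks_truth(self, small_movie, small_movie_maps,
                                        small_movie_seeds):
        params, stack, truth = small_movie
        traj = track_trajectory(stack, small_movie_maps, small_movie_seeds)
        wave = truth.waves[0]
        both = traj.wave_present & np.isfinite(wave.arc_um)
        assert both.sum() >= 5
        rmse = np.sqrt(np.mean(
            (traj.wave_arc_um[both] - wave.arc_um[both]) ** 2))
        assert rmse <= 2 * params.pixel_size_um * 2  # within 2 px RMS (um)

    def test_manual_correction_overrides(self, small_movie, small_movie_maps,
                                         small_movie_seeds):
        from dataclasses import replace

        params, stack, truth = small_movie
        seeds = SeedAnnotation(
            soma_point=small_movie_seeds.soma_point,
            hillock_point=small_movie_seeds.hillock_point,
            edge_point=small_movie_seeds.edge_point,
            corrections={2: {"wave": tuple(small_movie_seeds.hillock_point)}})
        traj = track_trajectory(stack, small_movie_maps, seeds)
        assert traj.wave_present[2]
        assert traj.wave_arc_um[2] < 15.0  # forced back to the hillock


class TestKymograph:
    def _stack(self, frames, px=0.5, dt=60.0):
        return CalibratedStack(frames=np.asarray(frames, dtype=float),
                               pixel_size_um=px, frame_interval_s=dt)

    def test_static_scene_rows_identical(self, rng):
        frame = rng.uniform(0, 100, size=(32, 64))
        stack = self._stack([frame] * 5)
        path = np.array([[16.0, 4.0], [16.0, 59.0]])
        kymo = build_kymograph(stack, path, half_width_px=2)
        assert np.allclose(kymo, kymo[0])

    def test_dimensions_contract(self, rng):
        stack = self._stack(rng.uniform(0, 1, size=(4, 32, 64)))
        path = np.array([[16.0, 4.0], [16.0, 59.0]])
        kymo = build_kymograph(stack, path)
        assert kymo.shape == (4, int(np.ceil(55.0)) + 1)

    def test_moving_bump_slope_recovers_speed(self):
        T, W = 30, 200
        px, dt = 0.5, 60.0
        v_um_min = 2.0  # um/min -> px/frame = v*dt/60/px
        frames = np.zeros((T, 32, W))
        cols = np.arange(W)
        for t in range(T):
            center = 20 + v_um_min * (dt / 60.0) * t / px
            frames[t, 14:19, :] = 50 * np.exp(-((cols - center) ** 2) / (2 * 4**2))
        stack = self._stack(frames, px=px, dt=dt)
        path = np.array([[16.0, 0.0], [16.0, W - 1.0]])
        kymo = build_kymograph(stack, path, half_width_px=2)
        peaks = kymo.argmax(axis=1)
        slope_px_per_frame = np.polyfit(np.arange(T), peaks, 1)[0]
        v_rec = slope_px_per_frame * px / (dt / 60.0)
        assert abs(v_rec - v_um_min) / v_um_min < 0.10

    def test_path_outside_frame_raises(self, rng):
        stack = self._stack(rng.uniform(0, 1, size=(2, 32, 64)))
        with pytest.raises(GeometryError):
            build_kymograph(stack, np.array([[16.0, 4.0], [16.0, 80.0]]))
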