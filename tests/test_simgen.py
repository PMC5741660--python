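"""Synthetic generators: determinism, planted regimes, ground-truth consistency."""

import numpy as np
import pytest

from wavetrack import simgen
from wavetrack.errors import GeometryError, ValidationError


class TestMovieSimulation:
    def test_seeded_determinism(self):
        p = dict(duration_min=20.0, image_shape=(96, 220), initial_length_um=60.0)
        s1, t1 = simgen.simulate_movie(simgen.movie_preset("paper-regime-20x", rng_seed=4, **p))
        s2, t2 = simgen.simulate_movie(simgen.movie_preset("paper-regime-20x", rng_seed=4, **p))
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(t1.length_um, t2.length_um)
        assert len(t1.waves) == len(t2.waves)
        for w1, w2 in zip(t1.waves, t2.waves):
            assert w1.speed_um_min == w2.speed_um_min

    def test_rate_zero_tip_advance(self):
        params = simgen.movie_preset(
            "paper-regime-20x", rng_seed=0, duration_min=100.0,
            frame_interval_s=300.0, wave_rate_per_h=1e-12,
            growth_speed_free_um_min=2.5, initial_length_um=30.0,
            image_shape=(160, 560))
        truth = simgen.simulate_dynamics(params)
        assert len(truth.waves) == 0
        advance = truth.length_um[-1] - truth.length_um[0]
        assert advance == pytest.approx(250.0, rel=1e-6)

    def test_speed_sampler_matches_regime(self):
        """Planted per-wave speeds across seeds center on 2.2 um/min."""
        speeds = []
        for seed in range(20):
            params = simgen.movie_preset(
                "paper-regime-20x", rng_seed=seed, duration_min=240.0,
                image_shape=(200, 600))
            truth = simgen.simulate_dynamics(params)
            speeds += [w.speed_um_min for w in truth.waves]
        speeds = np.asarray(speeds)
        se = speeds.std(ddof=1) / np.sqrt(speeds.size)
        assert abs(speeds.mean() - 2.2) < 3 * se + 1e-9

    def test_ground_truth_wave_speed_consistency(self):
        params = simgen.movie_preset("paper-regime-20x", rng_seed=6,
                                     duration_min=120.0)
        truth = simgen.simulate_dynamics(params)
        t_min = truth.times_s / 60.0
        checked = 0
        for w in truth.waves:
            fin = np.isfinite(w.arc_um) & (w.arc_um < truth.length_um - 1e-6)
            idx = np.flatnonzero(fin)
            for a, b in zip(idx[:-1], idx[1:]):
                v = (w.arc_um[b] - w.arc_um[a]) / (t_min[b] - t_min[a])
                assert v == pytest.approx(w.speed_um_min, abs=1e-6)
                checked += 1
        assert checked > 0

    def test_wave_arcs_within_neurite(self):
        params = simgen.movie_preset("paper-regime-20x", rng_seed=8,
                                     duration_min=180.0)
        truth = simgen.simulate_dynamics(params)
        for w in truth.waves:
            fin = np.isfinite(w.arc_um)
            assert np.all(w.arc_um[fin] >= 0)
            assert np.all(w.arc_um[fin] <= truth.length_um[fin] + 1e-9)

    def test_rendered_wave_centroid_matches_truth(self, small_movie):
        params, stack, truth = small_movie
        wave = truth.waves[0]
        frame = int(np.flatnonzero(np.isfinite(wave.arc_um))[3])
        with_wave = simgen.render_scene(params, truth, frame)
        truth_nowave = simgen.GroundTruth(
            times_s=truth.times_s, length_um=truth.length_um,
            gc_area_um2=truth.gc_area_um2, waves=[],
            soma_centroid_um=truth.soma_centroid_um,
            pixel_size_um=truth.pixel_size_um, backbone=truth.backbone,
            seeds=truth.seeds)
        without = simgen.render_scene(params, truth_nowave, frame)
        bump = with_wave - without
        rr, cc = np.mgrid[0:bump.shape[0], 0:bump.shape[1]]
        total = bump.sum()
        centroid = np.array([(bump * rr).sum() / total, (bump * cc).sum() / total])
        expected = truth.backbone.point(wave.arc_um[frame]) / params.pixel_size_um
        assert np.hypot(*(centroid - expected)) <= 1.0

    def test_wave_rate_within_poisson_ci(self):
        """Mean wave count across 50 seeded runs is consistent with the rate."""
        from wavetrack.validation import poisson_ci

        rate, hours = 2.5, 4.0
        total = 0
        for seed in range(50):
            params = simgen.movie_preset(
                "paper-regime-20x", rng_seed=1000 + seed,
                duration_min=hours * 60.0, image_shape=(200, 700))
            total += len(simgen.simulate_dynamics(params).waves)
        lo, hi = poisson_ci(total, 50 * hours)
        assert lo <= rate <= hi

    def test_validation_errors_name_fields(self):
        with pytest.raises(ValidationError, match="wave_rate_per_h"):
            simgen.SimMovieParams(wave_rate_per_h=-1)
        with pytest.raises(ValidationError, match="pixel_size_um"):
            simgen.SimMovieParams(pixel_size_um=0)
        with pytest.raises(GeometryError):
            simgen.SimMovieParams(neurite_backbone=[[50, -5], [50, 120]])

    def test_retraction_amplitude_in_regime(self):
        """Planted pulling amplitudes land in the 15-20 um range."""
        amps = []
        for seed in range(10):
            params = simgen.movie_preset(
                "paper-regime-20x", rng_seed=400 + seed, duration_min=240.0,
                image_shape=(200, 600))
            truth = simgen.simulate_dynamics(params)
            amps += [w.retraction_amplitude_um for w in truth.waves
                     if np.isfinite(w.retraction_amplitude_um)]
        amps = np.asarray(amps)
        assert amps.size > 5
        # single-wave retractions sit in the regime; chained ones may exceed it
        assert np.median(amps) == pytest.approx(15.0, abs=3.0)


class TestStedSimulation:
    def test_seeded_determinism(self):
        i1, t1, _ = simgen.simulate_sted_scene(simgen.sted_preset("sted-gc", rng_seed=2))
        i2, t2, _ = simgen.simulate_sted_scene(simgen.sted_preset("sted-gc", rng_seed=2))
        assert np.array_equal(i1, i2)
        assert t1.equals(t2)

    def test_zero_density_zero_puncta(self):
        params = simgen.sted_preset(
            "sted-gc", rng_seed=0,
            densities_per_um2={"GC_central_transition": 0.0, "GC_peripheral": 0.0})
        _, truth, _ = simgen.simulate_sted_scene(params)
        assert len(truth) == 0

    def test_poisson_count_sampling(self):
        """Planted counts in a 10 um^2 ROI at 5 /um^2 average to ~50."""
        roi = simgen.RoiSpec("neurite_proximal",
                             ((100, 100), (100, 260), (350, 260), (350, 100)))
        area = roi.area_um2(0.025)
        counts = []
        for seed in range(50):
            params = simgen.SimStedParams(
                image_shape=(512, 512), rois=(roi,),
                densities_per_um2={"neurite_proximal": 5.0 * 10.0 / area},
                rng_seed=seed)
            _, truth, _ = simgen.simulate_sted_scene(params)
            counts.append(len(truth))
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 50.0) < 3 * se + 1e-9

    def test_gc_preset_density_regime(self):
        params = simgen.sted_preset("sted-gc")
        assert params.densities_per_um2["GC_central_transition"] == pytest.approx(10.5)
        assert params.densities_per_um2["GC_peripheral"] == pytest.approx(0.9)

    def test_overlapping_roi_labels_rejected(self):
        with pytest.raises(GeometryError):
            simgen.SimStedParams(rois=(
                simgen.RoiSpec("AW_central_rear", ((10, 10), (10, 200), (200, 200), (200, 10))),
                simgen.RoiSpec("AW_central_front", ((50, 50), (50, 150), (150, 150), (150, 50))),
            ))

    def test_section_area_constraint(self):
        # 4 um^2 sections violate the 8-12 um^2 requirement
        small = ((0, 0), (0, 80), (80, 80), (80, 0))
        with pytest.raises(ValidationError):
            simgen.SimStedParams(rois=(
                simgen.RoiSpec("neurite_proximal", small),
                simgen.RoiSpec("neurite_distal", tuple((r + 200, c) for r, c in small)),
            ))


class TestLinescanTraces:
    def test_deterministic_and_shaped(self):
        pos1, tr1 = simgen.simulate_linescan_traces(4, rng_seed=7)
        pos2, tr2 = simgen.simulate_linescan_traces(4, rng_seed=7)
        assert np.array_equal(pos1, pos2)
        assert all(np.array_equal(a1, a2) and np.array_equal(m1, m2)
                   for (a1, m1), (a2, m2) in zip(tr1, tr2))
        assert len(tr1) == 4
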