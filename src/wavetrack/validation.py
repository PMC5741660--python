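"""Recovery benchmarks on the synthetic generator.

Every function here runs a self-contained experiment: generate scenes in the
default kinematic regime with known ground truth, run the analysis pipeline,
and measure how well the planted quantities are recovered.  The test suite
and the results-reproduction script both drive these; none of them reads
anything from disk.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from . import simgen
from .imageproc import make_feature_map
from .kinematics import (detect_pulling_events, elongation_vs_wave_count,
                         segment_wave_events)
from .linescan import LineScanTrace, average_aligned_traces
from .morphometry import gc_wave_response, region_area_timecourse
from .puncta import classify_tendency, detect_puncta, roi_densities
from .tracking import SeedAnnotation, track_trajectory

__all__ = [
    "track_simulated_movie",
    "wave_speed_recovery",
    "frequency_recovery",
    "poisson_ci",
    "pulling_detection_stats",
    "elongation_cohort",
    "linescan_offset_recovery",
    "puncta_recovery",
    "tendency_match_rate",
    "gc_response_recovery",
]


def track_simulated_movie(params: simgen.SimMovieParams):
    """Render a movie, build feature maps, track it; returns (traj, truth)."""
    stack, truth = simgen.simulate_movie(params)
    maps = [make_feature_map(frame) for frame in stack.frames]
    seeds = SeedAnnotation(
        soma_point=truth.seeds["soma"], hillock_point=truth.seeds["hillock"],
        edge_point=truth.seeds["edge"], wave_point=truth.seeds["wave"])
    traj = track_trajectory(stack, maps, seeds)
    return traj, truth


def _match_speed_pairs(traj, events, truth, max_mismatch_um=10.0):
    """Pair tracked wave events with planted waves by arc-position overlap."""
    pairs = []
    for ev in events:
        frames = np.arange(ev.start_frame, ev.end_frame + 1)
        s_tracked = traj.wave_arc_um[frames]
        best, best_d = None, max_mismatch_um
        for w in truth.waves:
            s_true = w.arc_um[frames]
            both = np.isfinite(s_tracked) & np.isfinite(s_true)
            if both.sum() < 2:
                continue
            d = float(np.mean(np.abs(s_tracked[both] - s_true[both])))
            if d < best_d:
                best, best_d = w, d
        if best is not None:
            pairs.append((best.speed_um_min, ev.velocity_um_min))
    return pairs


def wave_speed_recovery(n_movies: int = 20, base_seed: int = 0, **overrides):
    """Full-pipeline per-wave speed recovery in the default regime.

    Returns ``(planted, recovered)`` arrays over all matched waves of
    ``n_movies`` seeded movies.
    """
    planted, recovered = [], []
    for k in range(n_movies):
        params = simgen.movie_preset("paper-regime-20x",
                                     rng_seed=base_seed + k, **overrides)
        traj, truth = track_simulated_movie(params)
        events = segment_wave_events(traj)
        for v_true, v_rec in _match_speed_pairs(traj, events, truth):
            planted.append(v_true)
            recovered.append(v_rec)
    return np.asarray(planted), np.asarray(recovered)


def poisson_ci(count: int, exposure: float, level: float = 0.95):
    """Exact (Garwood) Poisson confidence interval for a rate."""
    alpha = 1 - level
    lo = sps.chi2.ppf(alpha / 2, 2 * count) / 2 if count > 0 else 0.0
    hi = sps.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return lo / exposure, hi / exposure


def frequency_recovery(n_movies: int = 20, rate_per_h: float = 2.5,
                       duration_h: float = 8.0, base_seed: int = 0):
    """Pooled wave-frequency estimate vs the exact Poisson 95% CI.

    Uses the dynamics path (the counting statistic does not depend on the
    renderer).  Returns ``(rate_hat, ci_lo, ci_hi)``.
    """
    total = 0
    for k in range(n_movies):
        params = simgen.movie_preset(
            "paper-regime-20x", rng_seed=base_seed + k,
            duration_min=duration_h * 60.0, image_shape=(200, 900),
            wave_rate_per_h=rate_per_h)
        truth = simgen.simulate_dynamics(params)
        total += len(truth.waves)
    exposure = n_movies * duration_h
    lo, hi = poisson_ci(total, exposure)
    return total / exposure, lo, hi


def pulling_detection_stats(n_movies: int = 20, base_seed: int = 100,
                            min_amplitude_um: float = 5.0,
                            match_tol_min: float = 10.0):
    """Sensitivity / false-positive fraction / amplitude error of the
    pulling-event detector against the planted retraction ledger."""
    tp = fp = fn = 0
    amp_errors = []
    for k in range(n_movies):
        params = simgen.movie_preset(
            "paper-regime-20x", rng_seed=base_seed + k,
            duration_min=240.0, image_shape=(200, 600))
        truth = simgen.simulate_dynamics(params)
        t_min = truth.times_s / 60.0
        if truth.waves:
            s_mat = np.column_stack([w.arc_um for w in truth.waves])
        else:
            s_mat = np.full((t_min.size, 1), np.nan)
        detected = detect_pulling_events(t_min, truth.length_um, s_mat,
                                         min_amplitude_um=min_amplitude_um)
        planted = simgen.planted_pulling_events(truth, min_amplitude_um)
        matched: set[int] = set()
        for ev in detected:
            best, best_d = None, match_tol_min
            for i, (t0, _) in enumerate(planted):
                if i in matched:
                    continue
                d = abs(ev.time_min - t0)
                if d < best_d:
                    best, best_d = i, d
            if best is None:
                fp += 1
            else:
                matched.add(best)
                tp += 1
                amp_errors.append(
                    abs(ev.amplitude_um - planted[best][1]) / planted[best][1])
        fn += len(planted) - len(matched)
    sensitivity = tp / (tp + fn) if tp + fn else math.nan
    fp_fraction = fp / (tp + fp) if tp + fp else 0.0
    return sensitivity, fp_fraction, float(np.mean(amp_errors))


def elongation_cohort(n_neurites: int = 50, duration_h: float = 8.0,
                      base_seed: int = 300, rate_max_per_h: float = 4.0):
    """Elongation-vs-wave-count cohort (dynamics path).

    Wave rates vary across neurites (uniform up to ``rate_max_per_h``) so the
    cohort spans wave-free rapid growers and wave-rich stallers.  Returns
    ``(table, rho, p)``.
    """
    rng = np.random.default_rng(base_seed)
    cohort = []
    for k in range(n_neurites):
        rate = max(float(rng.uniform(0.0, rate_max_per_h)), 1e-9)
        params = simgen.movie_preset(
            "paper-regime-20x", rng_seed=base_seed + 1 + k,
            duration_min=duration_h * 60.0, image_shape=(200, 900),
            wave_rate_per_h=rate)
        truth = simgen.simulate_dynamics(params)
        cohort.append((truth.length_um, len(truth.waves)))
    return elongation_vs_wave_count(cohort)


def linescan_offset_recovery(n_traces: int = 16, offset_um: float = 5.0,
                             rng_seed: int = 0):
    """Planted actin-myosin peak offset after alignment and averaging."""
    pos, raw = simgen.simulate_linescan_traces(
        n_traces, myosin_offset_um=offset_um, rng_seed=rng_seed)
    traces = [
        LineScanTrace(positions_um=pos, intensities=np.vstack(pair),
                      channels=("actin", "myosin"))
        for pair in raw
    ]
    grid, mean, _ = average_aligned_traces(traces)
    actin_peak = grid[int(np.argmax(mean[0]))]
    myosin_peak = grid[int(np.argmax(mean[1]))]
    return float(actin_peak - myosin_peak)


def puncta_recovery(presets=("sted-aw", "sted-gc"), n_scenes: int = 20,
                    base_seed: int = 0):
    """Per-ROI relative count error vs each scene's planted puncta table.

    Returns a dict label -> array of signed relative errors.
    """
    errors: dict[str, list[float]] = {}
    for preset in presets:
        for k in range(n_scenes):
            params = simgen.sted_preset(preset, rng_seed=base_seed + k)
            image, truth, rois = simgen.simulate_sted_scene(params)
            centroids = detect_puncta(image[1], params.pixel_size_um)
            records = roi_densities(centroids, rois, params.pixel_size_um)
            for rec in records:
                n_planted = int((truth["label"] == rec.label).sum())
                if n_planted == 0:
                    continue
                errors.setdefault(rec.label, []).append(
                    (rec.count - n_planted) / n_planted)
    return {k: np.asarray(v) for k, v in errors.items()}


def tendency_match_rate(n_pairs: int = 200, contrast: float = 0.20,
                        measurement_cv: float = 0.03, rng_seed: int = 1):
    """Fraction of planted rear/front tendency labels recovered.

    Density pairs are drawn with the given +-``contrast``; measured densities
    carry a small relative measurement error (``measurement_cv``).
    """
    rng = np.random.default_rng(rng_seed)
    correct = 0
    for _ in range(n_pairs):
        base = rng.uniform(3.0, 10.0)
        label = "increase" if rng.random() < 0.5 else "decrease"
        other = base * (1 + contrast if label == "increase" else 1 - contrast)
        a = base * (1 + rng.normal(0, measurement_cv))
        b = other * (1 + rng.normal(0, measurement_cv))
        correct += classify_tendency(a, b) == label
    return correct / n_pairs


def gc_response_recovery(rng_seed: int = 5):
    """Fold change and % loss recovered from a rendered single-wave movie.

    Plants the default regime: two-fold area increase at merge and a 50%
    decay of the peak over 45 min.  Returns ``(fold, loss_pct)``.
    """
    params = simgen.movie_preset(
        "paper-regime-20x", rng_seed=rng_seed, duration_min=150.0,
        frame_interval_s=60.0, wave_times_min=[20.0], wave_rate_per_h=1e-9)
    stack, truth = simgen.simulate_movie(params)
    wave = truth.waves[0]
    tip0 = tuple(int(x) for x in np.round(
        truth.backbone.point(truth.length_um[0]) / params.pixel_size_um))
    areas = region_area_timecourse(stack, tip0, window_px=30)
    (fold, loss), = gc_wave_response(areas, [wave.merge_min * 60.0])
    return fold, loss
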