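"""End-to-end pipeline: denoise -> feature maps -> trajectory -> kinematics ->
morphometry, with a machine-readable run manifest.

Re-running with the same config and inputs reproduces all numeric outputs
bit-identically (no wall-clock values enter the CSV/JSON payloads; the
manifest carries the config hash and seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig, config_hash
from .errors import WavetrackError
from .imageproc import CalibratedStack, PCParams, make_feature_map
from .io import write_trajectory
from .kinematics import (detect_pulling_events, frequency_velocity_timecourse,
                         segment_wave_events, summarize)
from .morphometry import gc_wave_response, region_area_timecourse
from .tracking import SeedAnnotation, track_trajectory

logger = logging.getLogger("wavetrack")

__all__ = ["run_pipeline", "compute_feature_maps"]


def compute_feature_maps(stack: CalibratedStack, cfg: dict) -> list:
    """Denoised phase-congruency feature map for every frame."""
    params = PCParams(
        n_scales=cfg["n_scales"], n_orientations=cfg["n_orientations"],
        min_wavelength=cfg["min_wavelength"], scale_multiplier=cfg["scale_multiplier"],
        filter_bandwidth=cfg["filter_bandwidth"], noise_k=cfg["noise_k"],
        epsilon=cfg["epsilon"], pc_threshold=cfg["pc_threshold"],
    )
    maps = []
    for t in range(stack.n_frames):
        logger.debug("feature map: frame %d/%d", t + 1, stack.n_frames)
        maps.append(make_feature_map(
            stack.frames[t], params,
            min_object_px=cfg["min_object_px"],
            background_percentile=cfg["background_percentile"],
        ))
    return maps


def _stage(name, frame=None):
    suffix = f" (frame {frame})" if frame is not None else ""
    return f"stage {name}{suffix}"


def run_pipeline(config: PipelineConfig, stack: CalibratedStack,
                 seeds: SeedAnnotation, out_dir=None) -> dict:
    """Run all stages on one movie; write CSV/JSON outputs; return the bundle."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    try:
        logger.info("feature maps (%d frames)", stack.n_frames)
        maps = compute_feature_maps(stack, config["imageproc"])
    except WavetrackError as err:
        raise type(err)(f"{_stage('imageproc')}: {err}") from err

    tcfg = config["tracking"]
    try:
        logger.info("tracking")
        traj = track_trajectory(
            stack, maps, seeds,
            search_radius_px=tcfg["search_radius_px"],
            denoise_sigma_px=config["imageproc"]["denoise_sigma_px"],
            soma_max_radius_px=tcfg["soma_max_radius_px"],
            wave_min_factor=tcfg["wave_min_factor"],
            wave_prominence_factor=tcfg["wave_prominence_factor"],
            soma_exclude_um=tcfg["soma_exclude_um"],
            tip_exclude_um=tcfg["tip_exclude_um"],
        )
    except WavetrackError as err:
        raise type(err)(f"{_stage('tracking')}: {err}") from err
    bundle["trajectory"] = traj
    write_trajectory(traj, out / "trajectory.csv")

    kcfg = config["kinematics"]
    events = segment_wave_events(
        traj, backward_jump_um=kcfg["backward_jump_um"],
        max_gap_frames=kcfg["max_gap_frames"],
        completed_tol_um=kcfg["completed_tol_um"], min_samples=kcfg["min_samples"])
    pulling = detect_pulling_events(
        traj.times_s / 60.0, traj.length_um, traj.wave_arc_um,
        min_amplitude_um=kcfg["min_amplitude_um"],
        approach_window_um=kcfg["approach_window_um"])
    summary = summarize(traj, events, pulling)
    bundle["events"] = events
    bundle["pulling"] = pulling
    bundle["summary"] = summary

    import pandas as pd

    pd.DataFrame([{
        "start_min": e.start_min, "end_min": e.end_min,
        "distance_um": e.distance_um, "duration_min": e.duration_min,
        "velocity_um_min": e.velocity_um_min, "completed": e.completed,
    } for e in events]).to_csv(out / "wave_events.csv", index=False)
    pd.DataFrame([{
        "time_min": p.time_min, "trough_min": p.trough_min,
        "amplitude_um": p.amplitude_um,
    } for p in pulling]).to_csv(out / "pulling_events.csv", index=False)

    span_min = (traj.times_s[-1] - traj.times_s[0]) / 60.0
    if span_min >= 2 * kcfg["window_min"]:
        tc, r, p = frequency_velocity_timecourse(traj, events, kcfg["window_min"])
        tc.to_csv(out / "frequency_velocity.csv", index=False)
        bundle["freq_vel_corr"] = (r, p)

    # GC area time course, seeded at the tracked frame-0 edge.
    mcfg = config["morphometry"]
    edge0 = tuple(np.round(traj.edge_rc[0]).astype(int))
    try:
        areas = region_area_timecourse(stack, edge0, window_px=mcfg["window_px"])
    except WavetrackError as err:
        raise type(err)(f"{_stage('morphometry')}: {err}") from err
    bundle["areas"] = areas
    pd.DataFrame({"time_s": areas.times_s, "area_um2": areas.areas_um2,
                  "gap": areas.gap}).to_csv(out / "gc_areas.csv", index=False)
    arrivals_s = np.array([e.end_min * 60.0 for e in events if e.completed])
    if arrivals_s.size:
        bundle["gc_response"] = gc_wave_response(
            areas, arrivals_s, window_min=mcfg["pre_post_window_min"],
            loss_window_min=tuple(mcfg["loss_window_min"]))

    summary_payload = {
        "frequency_per_h": summary.frequency_per_h,
        "velocity_mean_um_min": summary.velocity_mean,
        "velocity_sem_um_min": summary.velocity_sem,
        "net_elongation_um": summary.net_elongation_um,
        "n_waves": len(events),
        "n_pulling_events": len(pulling),
    }
    (out / "summary.json").write_text(json.dumps(summary_payload, indent=1))

    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "wavetrack_version": __version__,
        "numpy_version": np.__version__,
        "n_frames": stack.n_frames,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
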