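"""Readers and writers shared by all pipeline stages.

Rasters are TIFF (multi-page for movies, two-page for two-channel STED
stills) with a JSON sidecar carrying the calibration; annotations, seeds and
ROIs are JSON; tables are CSV.  Every writer has a paired reader that
recovers its fields losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .imageproc import CalibratedStack
from .simgen import GroundTruth, RoiSpec, WaveRecord
from .tracking import SeedAnnotation, Trajectory

__all__ = [
    "write_stack", "read_stack",
    "write_seeds", "read_seeds",
    "write_rois", "read_rois",
    "write_trajectory", "read_trajectory",
    "write_ground_truth", "read_ground_truth",
    "write_kymograph", "read_kymograph",
]


def _sidecar_path(tiff_path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + ".json")


def write_stack(stack: CalibratedStack, tiff_path) -> None:
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel_labels": list(stack.channel_labels) if stack.channel_labels else None,
    }
    _sidecar_path(tiff_path).write_text(json.dumps(meta, indent=1))


def read_stack(tiff_path) -> CalibratedStack:
    frames = np.asarray(tifffile.imread(tiff_path), dtype=float)
    side = _sidecar_path(tiff_path)
    if not side.exists():
        raise ValidationError(f"missing calibration sidecar {side}")
    meta = json.loads(side.read_text())
    labels = meta.get("channel_labels")
    return CalibratedStack(
        frames=frames,
        pixel_size_um=meta["pixel_size_um"],
        frame_interval_s=meta["frame_interval_s"],
        channel_labels=tuple(labels) if labels else None,
    )


def write_seeds(seeds: SeedAnnotation, path) -> None:
    payload = {
        "soma_point": list(seeds.soma_point),
        "hillock_point": list(seeds.hillock_point),
        "edge_point": list(seeds.edge_point),
        "wave_point": list(seeds.wave_point) if seeds.wave_point else None,
        "corrections": {
            str(f): {k: list(v) for k, v in c.items()}
            for f, c in seeds.corrections.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_seeds(path) -> SeedAnnotation:
    d = json.loads(Path(path).read_text())
    return SeedAnnotation(
        soma_point=tuple(d["soma_point"]),
        hillock_point=tuple(d["hillock_point"]),
        edge_point=tuple(d["edge_point"]),
        wave_point=tuple(d["wave_point"]) if d.get("wave_point") else None,
        corrections={
            int(f): {k: tuple(v) for k, v in c.items()}
            for f, c in d.get("corrections", {}).items()
        },
    )


def write_rois(rois: list[RoiSpec], path) -> None:
    payload = [
        {"label": r.label, "polygon_px": [list(p) for p in r.polygon_px]} for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path) -> list[RoiSpec]:
    data = json.loads(Path(path).read_text())
    return [
        RoiSpec(label=d["label"],
                polygon_px=tuple(tuple(p) for p in d["polygon_px"]))
        for d in data
    ]


def write_trajectory(traj: Trajectory, path) -> None:
    df = traj.to_dataframe()
    df["pixel_size_um"] = traj.pixel_size_um
    df.to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory.from_dataframe(df, pixel_size_um=float(df["pixel_size_um"].iloc[0]))


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Documented JSON ground-truth/annotation layout (see README)."""
    payload = {
        "times_s": truth.times_s.tolist(),
        "length_um": truth.length_um.tolist(),
        "gc_area_um2": truth.gc_area_um2.tolist(),
        "soma_centroid_um": truth.soma_centroid_um.tolist(),
        "pixel_size_um": truth.pixel_size_um,
        "seeds": {k: (list(v) if v is not None else None)
                  for k, v in truth.seeds.items()},
        "backbone_points_um": truth.backbone.points_um.tolist(),
        "waves": [
            {
                "inception_min": w.inception_min,
                "speed_um_min": w.speed_um_min,
                "completed": w.completed,
                "merge_min": w.merge_min,
                "retraction_start_min": w.retraction_start_min,
                "retraction_amplitude_um": w.retraction_amplitude_um,
                "arc_um": [None if np.isnan(x) else x for x in w.arc_um],
            }
            for w in truth.waves
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> dict:
    """Ground truth as plain arrays (waves as WaveRecord list)."""
    d = json.loads(Path(path).read_text())
    waves = [
        WaveRecord(
            inception_min=w["inception_min"], speed_um_min=w["speed_um_min"],
            completed=w["completed"], merge_min=w["merge_min"],
            retraction_start_min=w["retraction_start_min"],
            retraction_amplitude_um=w["retraction_amplitude_um"],
            arc_um=np.array([np.nan if x is None else x for x in w["arc_um"]]),
        )
        for w in d["waves"]
    ]
    return {
        "times_s": np.asarray(d["times_s"], dtype=float),
        "length_um": np.asarray(d["length_um"], dtype=float),
        "gc_area_um2": np.asarray(d["gc_area_um2"], dtype=float),
        "soma_centroid_um": np.asarray(d["soma_centroid_um"], dtype=float),
        "pixel_size_um": d["pixel_size_um"],
        "seeds": d["seeds"],
        "backbone_points_um": np.asarray(d["backbone_points_um"], dtype=float),
        "waves": waves,
    }


def write_kymograph(kymo: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(kymo, dtype=np.float32),
                     photometric="minisblack")


def read_kymograph(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
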