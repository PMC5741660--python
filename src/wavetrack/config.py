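"""Pipeline configuration: per-module parameter blocks with strict validation.

Every parameter has a documented default equal to the module-level defaults;
unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["DEFAULTS", "PipelineConfig", "load_config", "config_hash"]


DEFAULTS: dict = {
    "simgen": {
        "preset": "paper-regime-20x",
        "overrides": {},
    },
    "imageproc": {
        "denoise_sigma_px": 1.0,
        "n_scales": 4,
        "n_orientations": 6,
        "min_wavelength": 3.0,
        "scale_multiplier": 2.1,
        "filter_bandwidth": 0.55,
        "noise_k": 2.0,
        "epsilon": 1e-4,
        "pc_threshold": 0.3,
        "min_object_px": 20,
        "background_percentile": 5.0,
    },
    "tracking": {
        "search_radius_px": 15.0,
        "soma_max_radius_px": 25.0,
        "wave_min_factor": 1.5,
        "wave_prominence_factor": 1.0,
        "soma_exclude_um": 12.0,
        "tip_exclude_um": 15.0,
        "kymo_half_width_px": 3.0,
    },
    "kinematics": {
        "backward_jump_um": 10.0,
        "max_gap_frames": 2,
        "completed_tol_um": 25.0,
        "min_samples": 3,
        "min_amplitude_um": 5.0,
        "approach_window_um": 20.0,
        "window_min": 60.0,
        "complete_only": False,
    },
    "morphometry": {
        "window_px": 40,
        "pre_post_window_min": 10.0,
        "loss_window_min": [30.0, 60.0],
    },
    "linescan": {
        "sampling_step_um": 0.25,
        "smoothing_window": 5,
        "normalize": True,
        "background_percentile": 5.0,
    },
    "puncta": {
        "background_percentile": 50.0,
        "intensity_threshold": None,
        "min_diameter_nm": 40.0,
        "max_diameter_nm": 400.0,
        "stability_band": 0.12,
        "normalize": True,
    },
    "stats": {
        "test": "t",
    },
}


@dataclass
class PipelineConfig:
    blocks: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    verbosity: str = "info"

    def __post_init__(self) -> None:
        self.blocks = _merge_with_defaults(self.blocks)

    def __getitem__(self, module: str) -> dict:
        return self.blocks[module]


def _merge_with_defaults(user: dict) -> dict:
    merged = {}
    for module, defaults in DEFAULTS.items():
        block = dict(defaults)
        given = user.get(module, {})
        if not isinstance(given, dict):
            raise ValidationError(f"config block {module!r}: expected a mapping")
        for key, value in given.items():
            if key not in defaults:
                raise ValidationError(f"config: unknown key {module}.{key}")
            block[key] = value
        merged[module] = block
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValidationError(f"config: unknown module blocks {sorted(unknown)}")
    return merged


def load_config(path=None, seed: int = 0, out_dir: str = ".") -> PipelineConfig:
    """Load a YAML config (or the pure defaults when ``path`` is None)."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ValidationError("config: top level must be a mapping")
    seed = int(user.pop("seed", seed))
    out_dir = str(user.pop("out_dir", out_dir))
    verbosity = str(user.pop("verbosity", "info"))
    return PipelineConfig(blocks=user, seed=seed, out_dir=out_dir, verbosity=verbosity)


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of all parameters (changes iff any parameter changes)."""
    canonical = json.dumps(
        {"blocks": config.blocks, "seed": config.seed}, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()
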