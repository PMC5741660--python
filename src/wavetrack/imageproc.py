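"""Denoising, background handling and phase-congruency line detection.

The neurite detector follows the classical log-Gabor phase-congruency
construction: an image is decomposed with a bank of log-Gabor quadrature
filters over ``n_scales`` scales and ``n_orientations`` orientations; at each
pixel the agreement of the local phase across scales, weighted by the spread
of filter responses and compensated for an estimated noise floor, gives a
contrast-invariant feature significance in [0, 1].  Line structures such as
neurites stand out regardless of their absolute brightness, which is what
makes the same binarization threshold usable across frames of a bleaching,
unevenly lit time-lapse movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import remove_small_objects

from .errors import ValidationError

__all__ = [
    "CalibratedStack",
    "PCParams",
    "FeatureMap",
    "gaussian_denoise",
    "phase_congruency",
    "make_feature_map",
]


@dataclass
class CalibratedStack:
    """A time-ordered intensity grid with spatial and temporal calibration.

    Parameters
    ----------
    frames
        ``(T, H, W)`` non-negative intensities.  A single image may be passed
        as ``(H, W)`` and is promoted to one frame.
    pixel_size_um
        Physical pixel pitch in micrometres.
    frame_interval_s
        Time between consecutive frames, seconds.
    channel_labels
        Optional per-channel labels when frames carry channels.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("frames: expected (T, H, W) with T >= 1")
        if not np.all(np.isfinite(self.frames)) or self.frames.min() < 0:
            raise ValidationError("frames: intensities must be finite and >= 0")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um: must be > 0")
        if not self.frame_interval_s > 0:
            raise ValidationError("frame_interval_s: must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def times_s(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * float(self.frame_interval_s)


@dataclass(frozen=True)
class PCParams:
    """Parameters of the log-Gabor phase-congruency detector.

    ``noise_k`` scales the Rayleigh-based noise threshold ``T`` estimated from
    the smallest-scale amplitude response; ``epsilon`` stabilizes the division
    by total amplitude; ``pc_threshold`` binarizes the [0, 1] map.
    """

    n_scales: int = 4
    n_orientations: int = 6
    min_wavelength: float = 3.0
    scale_multiplier: float = 2.1
    filter_bandwidth: float = 0.55
    noise_k: float = 2.0
    epsilon: float = 1e-4
    pc_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValidationError("n_scales/n_orientations: counts must be >= 1")
        if self.min_wavelength < 2:
            raise ValidationError("min_wavelength: must be >= 2 px")
        if self.scale_multiplier <= 1:
            raise ValidationError("scale_multiplier: must be > 1")
        if not 0 < self.filter_bandwidth < 1:
            raise ValidationError("filter_bandwidth: must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValidationError("epsilon: must be > 0")
        if not 0 < self.pc_threshold < 1:
            raise ValidationError("pc_threshold: must lie in (0, 1)")


@dataclass
class FeatureMap:
    """Phase-congruency map plus its binarization and provenance."""

    pc: np.ndarray
    binary: np.ndarray
    params: PCParams
    min_object_px: int = 0


def gaussian_denoise(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Convolve with a unit-sum isotropic Gaussian (reflective boundaries)."""
    if not sigma_px > 0:
        raise ValidationError("sigma_px: must be > 0")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValidationError("image: values must be finite")
    return gaussian_filter(image, sigma=sigma_px, mode="reflect")


# ---------------------------------------------------------------------------
# log-Gabor filter bank (cached per (shape, params) since movies reuse it
# for every frame)
# ---------------------------------------------------------------------------

_BANK_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _filter_bank(shape: tuple[int, int], params: PCParams):
    key = (shape, params.n_scales, params.n_orientations, params.min_wavelength,
           params.scale_multiplier, params.filter_bandwidth)
    hit = _BANK_CACHE.get(key)
    if hit is not None:
        return hit
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # avoid log(0); the DC entry of every filter is zeroed
    theta = np.arctan2(-fy, fx)
    sintheta, costheta = np.sin(theta), np.cos(theta)

    # Butterworth low-pass keeps the largest-scale filters from wrapping at
    # the Nyquist corners.
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    log_sigma = np.log(params.filter_bandwidth)
    radial = np.empty((params.n_scales, rows, cols))
    for s in range(params.n_scales):
        wavelength = params.min_wavelength * params.scale_multiplier ** s
        f0 = 1.0 / wavelength
        radial[s] = np.exp(-(np.log(radius / f0) ** 2) / (2 * log_sigma**2)) * lowpass
        radial[s, 0, 0] = 0.0

    theta_sigma = np.pi / params.n_orientations / 1.2
    angular = np.empty((params.n_orientations, rows, cols))
    for o in range(params.n_orientations):
        angle = o * np.pi / params.n_orientations
        ds = sintheta * np.cos(angle) - costheta * np.sin(angle)
        dc = costheta * np.cos(angle) + sintheta * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        angular[o] = np.exp(-(dtheta**2) / (2 * theta_sigma**2))

    _BANK_CACHE[key] = (radial, angular)
    return radial, angular


def phase_congruency(image: np.ndarray, params: PCParams | None = None) -> np.ndarray:
    """Phase-congruency map in [0, 1]; high values mark lines and edges.

    A constant image is a defined (all ~0) case, not an error.  The output is
    invariant, up to a small tolerance at feature pixels, to multiplying the
    input by a positive constant: amplitudes, energies and the estimated noise
    threshold all scale linearly so their ratio is preserved.
    """
    if params is None:
        params = PCParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValidationError("image: expected a 2-D grid of at least 16x16")

    radial, angular = _filter_bank(image.shape, params)
    IM = np.fft.fft2(image - image.mean())
    eps = params.epsilon

    total_energy = np.zeros(image.shape)
    total_sum_an = np.zeros(image.shape)

    for o in range(params.n_orientations):
        e_scale = []
        o_scale = []
        sum_e = np.zeros(image.shape)
        sum_o = np.zeros(image.shape)
        sum_an = np.zeros(image.shape)
        max_an = np.zeros(image.shape)
        tau = 0.0
        for s in range(params.n_scales):
            eo = np.fft.ifft2(IM * (radial[s] * angular[o]))
            an = np.abs(eo)
            e_scale.append(eo.real)
            o_scale.append(eo.imag)
            sum_e += eo.real
            sum_o += eo.imag
            sum_an += an
            np.maximum(max_an, an, out=max_an)
            if s == 0:
                # Rayleigh scale of the smallest-scale amplitude response.
                tau = float(np.median(an)) / np.sqrt(np.log(4))

        x_energy = np.sqrt(sum_e**2 + sum_o**2) + eps
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros(image.shape)
        for es, os_ in zip(e_scale, o_scale):
            energy += es * mean_e + os_ * mean_o - np.abs(es * mean_o - os_ * mean_e)

        # Expected noise energy assuming the filter amplitudes fall off
        # geometrically with scale; threshold = mean + noise_k * sd.
        m = 1.0 / params.scale_multiplier
        total_tau = tau * (1 - m**params.n_scales) / (1 - m)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sd = total_tau * np.sqrt((4 - np.pi) / 2)
        T = noise_mean + params.noise_k * noise_sd
        energy = np.maximum(energy - T, 0.0)

        # Weight down pixels responding at only one scale (noise-like).
        if params.n_scales > 1:
            width = (sum_an / (max_an + eps) - 1) / (params.n_scales - 1)
        else:
            width = np.ones(image.shape)
        weight = 1.0 / (1.0 + np.exp(10.0 * (0.5 - width)))

        total_energy += weight * energy
        total_sum_an += sum_an

    pc = total_energy / (total_sum_an + eps)
    return np.clip(pc, 0.0, 1.0)


def make_feature_map(
    image: np.ndarray,
    params: PCParams | None = None,
    min_object_px: int = 20,
    background_percentile: float = 5.0,
) -> FeatureMap:
    """Background-subtract, run phase congruency, binarize, drop specks.

    An empty binary map is a legal result (blank field of view).
    """
    if params is None:
        params = PCParams()
    image = np.asarray(image, dtype=float)
    background = np.percentile(image, background_percentile)
    pc = phase_congruency(np.clip(image - background, 0, None), params)
    binary = pc >= params.pc_threshold
    if min_object_px > 0:
        binary = remove_small_objects(binary, max_size=int(min_object_px) - 1)
    return FeatureMap(pc=pc, binary=binary, params=replace(params), min_object_px=min_object_px)
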