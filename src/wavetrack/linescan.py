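"""Intensity profiles along neurites and wave-front half-maximum alignment.

Traces are aligned to the half-maximum of the wave front on the growth-cone
side (arc positions increase toward the GC), mean-normalized, smoothed and
averaged on a common grid with per-position SEM.  The half-max baseline is
the median of the lowest 10% of trace values — a reproducible stand-in for
the manual baseline judgement of interactive workflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .errors import CoverageError, GeometryError, ValidationError, WavetrackError

__all__ = [
    "LineScanTrace",
    "extract_linescan",
    "find_front_half_max",
    "average_aligned_traces",
]


class NoFrontError(WavetrackError, ValueError):
    """The trace has no wave front (flat, or peak below the baseline factor)."""


@dataclass
class LineScanTrace:
    """Sampled intensity along a neurite path, one or more channels.

    ``positions_um`` increase toward the growth cone.  ``intensities`` is
    ``(n_channels, n_samples)``.
    """

    positions_um: np.ndarray
    intensities: np.ndarray
    channels: tuple[str, ...] = ("actin",)
    alignment_offset_um: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValidationError("positions_um: must be strictly increasing")
        if self.intensities.shape[1] != self.positions_um.size:
            raise ValidationError("intensities: channels must match positions length")
        if len(self.channels) != self.intensities.shape[0]:
            raise ValidationError("channels: one label per channel")

    @property
    def step_um(self) -> float:
        return float(np.median(np.diff(self.positions_um)))


def extract_linescan(
    frame: np.ndarray,
    path_px: np.ndarray,
    sampling_step_um: float,
    pixel_size_um: float,
    channels: tuple[str, ...] = ("actin",),
    background_percentile: float = 5.0,
) -> LineScanTrace:
    """Background-subtracted intensity along a path, sampled by interpolation.

    ``frame`` is (H, W) or (C, H, W); the path runs soma -> growth cone, so
    the returned arc positions increase toward the GC.  The trace has
    ``floor(path length / step) + 1`` samples.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 2:
        frame = frame[None]
    if frame.shape[0] != len(channels):
        raise ValidationError("channels: one label per frame channel")
    path = np.asarray(path_px, dtype=float)
    h, w = frame.shape[1:]
    if (path[:, 0].min() < 0 or path[:, 1].min() < 0
            or path[:, 0].max() > h - 1 or path[:, 1].max() > w - 1):
        raise GeometryError("path escapes the frame")
    if not sampling_step_um > 0:
        raise ValidationError("sampling_step_um: must be > 0")

    seg = np.diff(path, axis=0)
    arc_px = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total_um = arc_px[-1] * pixel_size_um
    n = int(math.floor(total_um / sampling_step_um)) + 1
    s_um = np.arange(n) * sampling_step_um
    s_px = s_um / pixel_size_um
    rows = np.interp(s_px, arc_px, path[:, 0])
    cols = np.interp(s_px, arc_px, path[:, 1])
    out = np.empty((frame.shape[0], n))
    for ch in range(frame.shape[0]):
        background = np.percentile(frame[ch], background_percentile)
        out[ch] = map_coordinates(frame[ch], [rows, cols], order=1) - background
    return LineScanTrace(positions_um=s_um, intensities=out, channels=tuple(channels))


def find_front_half_max(
    trace: LineScanTrace | None = None,
    *,
    positions_um: np.ndarray | None = None,
    values: np.ndarray | None = None,
    channel: int = 0,
    min_peak_factor: float = 1.5,
) -> float:
    """Arc position of the half-maximum on the wave front (growth-cone side).

    The baseline is the median of the lowest 10% of values; the peak must
    exceed ``min_peak_factor`` x baseline spread above baseline, otherwise a
    :class:`NoFrontError` is raised.  The crossing of (baseline + peak)/2 is
    located by walking from the peak toward increasing arc (the GC side) and
    linearly interpolating; a profile that stays high to the end falls back
    to the rising edge of the front itself.
    """
    if trace is not None:
        pos = trace.positions_um
        y = trace.intensities[channel]
    else:
        pos = np.asarray(positions_um, dtype=float)
        y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise NoFrontError("trace too short")
    n_low = max(1, int(0.1 * y.size))
    baseline = float(np.median(np.sort(y)[:n_low]))
    peak_idx = int(np.argmax(y))
    peak = float(y[peak_idx])
    spread = peak - baseline
    if spread <= 0 or spread < 0.05 * max(abs(peak), 1e-12):
        raise NoFrontError("no wave front: trace is flat")
    if baseline > 0 and peak < min_peak_factor * baseline:
        raise NoFrontError("no wave front: peak does not exceed the baseline factor")
    half = baseline + 0.5 * spread

    below = np.flatnonzero(y[peak_idx:] < half)
    if below.size:
        j = peak_idx + below[0]
        x0, x1 = pos[j - 1], pos[j]
        y0, y1 = y[j - 1], y[j]
    else:
        # Profile stays above half to the trace end (step-like front):
        # use the rising edge just before the peak.
        above = np.flatnonzero(y[:peak_idx + 1] >= half)
        j = above[0]
        if j == 0:
            return float(pos[0])
        x0, x1 = pos[j - 1], pos[j]
        y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def average_aligned_traces(
    traces: list[LineScanTrace],
    smoothing_window: int = 5,
    normalize: bool = True,
    align_channel: int = 0,
):
    """Mean +- SEM profile per channel after normalization and front alignment.

    Each trace is divided by its per-channel mean intensity, smoothed with a
    moving average, shifted so its front half-maximum (of ``align_channel``)
    sits at arc 0, resampled to a common grid at the finest input step, and
    averaged.  Returns ``(grid_um, mean, sem)`` with ``mean``/``sem`` of shape
    ``(n_channels, n_grid)``.
    """
    if len(traces) < 2:
        raise ValidationError("average_aligned_traces: needs >= 2 traces")
    n_ch = traces[0].intensities.shape[0]
    step = min(tr.step_um for tr in traces)

    shifted = []
    for tr in traces:
        vals = tr.intensities.astype(float).copy()
        if normalize:
            means = vals.mean(axis=1, keepdims=True)
            if np.any(means <= 0):
                raise ValidationError("normalize: non-positive mean intensity")
            vals = vals / means
        if smoothing_window > 1:
            vals = uniform_filter1d(vals, size=smoothing_window, axis=1, mode="nearest")
        front = find_front_half_max(
            positions_um=tr.positions_um, values=vals[align_channel])
        shifted.append((tr.positions_um - front, vals))
        tr.alignment_offset_um = -front

    lo = max(p[0] for p, _ in shifted)
    hi = min(p[-1] for p, _ in shifted)
    if hi <= lo:
        raise CoverageError("aligned traces share no common arc support")
    grid = np.arange(lo, hi + step / 2, step)
    stackv = np.empty((len(shifted), n_ch, grid.size))
    for i, (p, vals) in enumerate(shifted):
        for ch in range(n_ch):
            stackv[i, ch] = np.interp(grid, p, vals[ch])
    mean = stackv.mean(axis=0)
    sem = stackv.std(axis=0, ddof=1) / math.sqrt(len(shifted))
    return grid, mean, sem
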