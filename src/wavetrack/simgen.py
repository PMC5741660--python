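"""Synthetic time-lapse movies and STED-like stills with known ground truth.

The movie generator emulates LifeAct-style epifluorescence acquisitions of a
developing neurite: a soma blob, a curvilinear neurite shaft, growth-cone-like
actin waves travelling anterogradely along the shaft, and a growth cone (GC)
at the tip that retracts toward an approaching wave, merges with it, transiently
doubles its area and then decays back.  Every quantity the analysis pipeline is
supposed to recover — neurite length, per-wave arc position and speed, GC area,
retraction amplitudes — is an explicit simulation state recorded frame by frame
in a :class:`GroundTruth` ledger, so recovery can be tested without any real
microscopy data.

Default kinematic regime (the study conditions): wave speeds drawn from a
normal with mean 2.2 and sd 0.4 um/min truncated positive, Poisson inception
at 2.5 waves/h, GC retraction of ~15 um starting when a wave comes within
20 um of the tip, a two-fold GC area increase on merge, and tip elongation of
0.9 um/min in wave-free epochs versus 0.5 um/min while waves transit.

The still generator emulates two-channel STED scenes: myosin-IIB puncta planted
at Poisson-random positions with region-wise densities inside labelled ROI
polygons, over an actin channel with declared per-ROI mean intensities.

All intensities are rendered as smooth photon scenes, then corrupted with
Poisson shot noise plus Gaussian read noise and clipped to a 12-bit range.
Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .errors import GeometryError, ValidationError
from .imageproc import CalibratedStack

__all__ = [
    "SimMovieParams",
    "WaveRecord",
    "GroundTruth",
    "SimStedParams",
    "RoiSpec",
    "simulate_movie",
    "simulate_dynamics",
    "render_scene",
    "simulate_sted_scene",
    "simulate_linescan_traces",
    "movie_preset",
    "sted_preset",
    "MOVIE_PRESETS",
    "STED_PRESETS",
]

_MAX_INTENSITY = 4095.0  # 12-bit camera range


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

def _default_backbone(image_shape, pixel_size_um, margin_um):
    """Gently curved left-to-right control polyline, centred vertically."""
    h_um = image_shape[0] * pixel_size_um
    w_um = image_shape[1] * pixel_size_um
    mid = h_um / 2
    cols = np.linspace(margin_um, w_um - margin_um, 6)
    rows = mid + np.array([0.0, -2.0, 2.5, -1.5, 2.0, 0.0])
    return np.column_stack([rows, cols])


@dataclass
class SimMovieParams:
    """Conditions of one simulated neurite movie.  Units in field names."""

    duration_min: float = 120.0
    frame_interval_s: float = 120.0
    pixel_size_um: float = 0.65
    image_shape: tuple[int, int] = (160, 360)
    neurite_backbone: np.ndarray | None = None  # (N, 2) control points, um (row, col)
    initial_length_um: float = 80.0
    wave_rate_per_h: float = 2.5
    wave_speed_mean_um_min: float = 2.2
    wave_speed_sd_um_min: float = 0.4
    wave_sigma_um: float = 3.0
    wave_lateral_sigma_um: float = 2.0
    gc_retraction_um: float = 15.0
    gc_area_fold_on_merge: float = 2.0
    gc_area_um2: float = 50.0
    gc_area_loss_frac: float = 0.5
    gc_area_decay_min: float = 45.0
    gc_area_hold_min: float = 10.0
    growth_speed_free_um_min: float = 0.9
    growth_speed_waves_um_min: float = 0.5
    approach_distance_um: float = 20.0
    merge_tolerance_um: float = 3.0
    soma_radius_um: float = 7.0
    hillock_arc_um: float = 8.0
    shaft_sigma_um: float = 0.5
    background_level: float = 100.0
    amplitude: float = 600.0
    read_noise_sd: float = 5.0
    rng_seed: int = 0
    # Optional deterministic wave inception times (minutes); overrides the
    # Poisson process.  Handy for planting a single scripted event.
    wave_times_min: Sequence[float] | None = None

    def __post_init__(self) -> None:
        positive = [
            "duration_min", "frame_interval_s", "pixel_size_um", "initial_length_um",
            "wave_speed_mean_um_min", "wave_speed_sd_um_min", "wave_sigma_um",
            "wave_lateral_sigma_um", "gc_retraction_um", "gc_area_fold_on_merge",
            "gc_area_um2", "gc_area_decay_min", "growth_speed_free_um_min",
            "growth_speed_waves_um_min", "approach_distance_um", "merge_tolerance_um",
            "soma_radius_um", "hillock_arc_um", "shaft_sigma_um", "amplitude",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name}: must be strictly positive")
        if self.wave_rate_per_h < 0:
            raise ValidationError("wave_rate_per_h: must be >= 0")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValidationError("background_level/read_noise_sd: must be >= 0")
        if self.n_frames < 2:
            raise ValidationError("duration_min/frame_interval_s: frame count must be >= 2")
        if self.neurite_backbone is None:
            self.neurite_backbone = _default_backbone(
                self.image_shape, self.pixel_size_um, margin_um=self._edge_margin_um()
            )
        self.neurite_backbone = np.asarray(self.neurite_backbone, dtype=float)
        if self.neurite_backbone.ndim != 2 or self.neurite_backbone.shape[0] < 2 \
                or self.neurite_backbone.shape[1] != 2:
            raise ValidationError("neurite_backbone: expected (N >= 2, 2) control points")
        seg = np.diff(self.neurite_backbone, axis=0)
        if np.hypot(seg[:, 0], seg[:, 1]).sum() < 20.0:
            raise ValidationError("neurite_backbone: total length must be >= 20 um")
        margin = self._edge_margin_um()
        h_um = self.image_shape[0] * self.pixel_size_um
        w_um = self.image_shape[1] * self.pixel_size_um
        r, c = self.neurite_backbone[:, 0], self.neurite_backbone[:, 1]
        if (r.min() < margin or c.min() < margin
                or r.max() > h_um - margin or c.max() > w_um - margin):
            raise GeometryError(
                "neurite_backbone exits the field of view (needs "
                f"{margin:.1f} um clearance from every border)"
            )

    def _edge_margin_um(self) -> float:
        gc_r = math.sqrt(self.gc_area_fold_on_merge * self.gc_area_um2 / math.pi)
        return max(3 * self.wave_lateral_sigma_um, gc_r + 2.0, self.soma_radius_um + 2.0)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min * 60.0 / self.frame_interval_s)) + 1


class _Backbone:
    """Arc-length parametrised curve through the control points."""

    def __init__(self, control_um: np.ndarray, step_um: float = 0.2):
        chord = np.concatenate(
            [[0.0], np.cumsum(np.hypot(*np.diff(control_um, axis=0).T))]
        )
        spline = CubicSpline(chord, control_um, axis=0)
        dense_t = np.linspace(0, chord[-1], max(int(chord[-1] / 0.05), 50))
        dense = spline(dense_t)
        arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))])
        self.total_um = float(arc[-1])
        self.s_um = np.arange(0.0, self.total_um, step_um)
        self.points_um = np.column_stack(
            [np.interp(self.s_um, arc, dense[:, 0]), np.interp(self.s_um, arc, dense[:, 1])]
        )

    def point(self, s_um: float) -> np.ndarray:
        """(row, col) in um at arc position ``s_um`` (clamped)."""
        s = np.clip(s_um, 0.0, self.s_um[-1])
        return np.array([
            np.interp(s, self.s_um, self.points_um[:, 0]),
            np.interp(s, self.s_um, self.points_um[:, 1]),
        ])


@dataclass
class WaveRecord:
    """One wave's birth, transit and fate."""

    inception_min: float
    speed_um_min: float
    arc_um: np.ndarray  # per-frame arc position from the soma centroid; NaN off-transit
    completed: bool
    merge_min: float = math.nan
    retraction_start_min: float = math.nan
    retraction_amplitude_um: float = math.nan


@dataclass
class GroundTruth:
    """Per-frame record of everything the pipeline should recover."""

    times_s: np.ndarray
    length_um: np.ndarray
    gc_area_um2: np.ndarray
    waves: list[WaveRecord]
    soma_centroid_um: np.ndarray  # (row, col) um
    pixel_size_um: float
    backbone: _Backbone
    seeds: dict  # frame-0 pixel annotations: soma/hillock/edge/wave (row, col)

    def backbone_polyline_um(self, frame: int) -> np.ndarray:
        """Occupied backbone (soma to tip) at ``frame``, um coordinates."""
        keep = self.backbone.s_um <= self.length_um[frame]
        return self.backbone.points_um[keep]

    def backbone_polyline_px(self, frame: int) -> np.ndarray:
        return self.backbone_polyline_um(frame) / self.pixel_size_um

    @property
    def soma_centroid_px(self) -> np.ndarray:
        return self.soma_centroid_um / self.pixel_size_um


# ---------------------------------------------------------------------------
# movie dynamics
# ---------------------------------------------------------------------------

def _truncated_positive_normal(rng, mean, sd):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise ValidationError("wave_speed_mean_um_min/sd: cannot draw a positive speed")


def simulate_dynamics(params: SimMovieParams) -> GroundTruth:
    """Integrate the tip/wave/GC-area state and return the ground-truth ledger.

    This is the fast path used both by :func:`simulate_movie` and by cohort
    studies that need trajectories without rendered frames.
    """
    rng = np.random.default_rng(params.rng_seed)
    backbone = _Backbone(params.neurite_backbone)
    l_max = backbone.total_um - 0.5
    l_min = max(params.hillock_arc_um + 2.0, 10.0)
    if params.initial_length_um > l_max:
        raise ValidationError("initial_length_um: exceeds the backbone length")

    # Wave inception times and speeds.
    if params.wave_times_min is not None:
        t_birth = sorted(float(t) for t in params.wave_times_min)
    else:
        t_birth = []
        t = 0.0
        rate_per_min = params.wave_rate_per_h / 60.0
        while rate_per_min > 0:
            t += rng.exponential(1.0 / rate_per_min)
            if t >= params.duration_min:
                break
            t_birth.append(t)
    speeds = [
        _truncated_positive_normal(rng, params.wave_speed_mean_um_min,
                                   params.wave_speed_sd_um_min)
        for _ in t_birth
    ]

    n_waves = len(t_birth)
    merged = [False] * n_waves
    merge_t = [math.nan] * n_waves
    retr_start = [math.nan] * n_waves
    retr_amount = [0.0] * n_waves
    retr_anchor = [math.nan] * n_waves  # L when retraction began

    # Retraction speed chosen so the planned amplitude is covered while the
    # wave closes the approach window (capped to stay finite when the window
    # is nearly all retraction).
    def retraction_speed(v):
        denom = params.approach_distance_um - params.merge_tolerance_um \
            - params.gc_retraction_um
        return params.gc_retraction_um * v / max(denom, 0.5)

    frame_dt_min = params.frame_interval_s / 60.0
    # Substep so that frame times are hit exactly.
    dt = frame_dt_min / max(1, int(math.ceil(frame_dt_min / 0.1)))
    n_frames = params.n_frames
    frame_times_min = np.arange(n_frames) * frame_dt_min

    length = np.empty(n_frames)
    merges_min: list[float] = []

    def wave_arc(i, t):
        return params.hillock_arc_um + speeds[i] * (t - t_birth[i])

    L = params.initial_length_um
    next_frame = 0
    t = 0.0
    eps = 1e-9
    while next_frame < n_frames:
        if t + eps >= frame_times_min[next_frame]:
            length[next_frame] = L
            next_frame += 1
            if next_frame >= n_frames:
                break
        active = [i for i in range(n_waves)
                  if t_birth[i] <= t and not merged[i]]
        gap = None
        lead = None
        for i in active:
            g = L - wave_arc(i, t)
            if gap is None or g < gap:
                gap, lead = g, i
        if lead is not None and gap <= params.merge_tolerance_um:
            merged[lead] = True
            merge_t[lead] = t
            merges_min.append(t)
            active.remove(lead)
            gap = None
            for i in active:
                g = L - wave_arc(i, t)
                if gap is None or g < gap:
                    gap, lead = g, i
        if lead is not None and gap is not None and gap <= params.approach_distance_um:
            if math.isnan(retr_start[lead]):
                retr_start[lead] = t
                retr_anchor[lead] = L
            dL = -retraction_speed(speeds[lead]) * dt
        elif active:
            dL = params.growth_speed_waves_um_min * dt
        else:
            dL = params.growth_speed_free_um_min * dt
        L = float(np.clip(L + dL, l_min, l_max))
        for i in active:
            if not math.isnan(retr_start[i]):
                retr_amount[i] = max(retr_amount[i], retr_anchor[i] - L)
        t += dt

    # GC area time course: baseline; on merge jump to fold x baseline, hold,
    # then linear decay of loss_frac of the peak over decay_min.
    area = np.full(n_frames, params.gc_area_um2)
    peak = params.gc_area_fold_on_merge * params.gc_area_um2
    for tm in merges_min:
        dt_post = frame_times_min - tm
        in_evt = dt_post >= 0
        frac = np.clip((dt_post - params.gc_area_hold_min) / params.gc_area_decay_min,
                       0.0, 1.0)
        val = peak * (1.0 - params.gc_area_loss_frac * frac)
        area[in_evt] = np.maximum(val[in_evt], params.gc_area_um2 * 0.2)

    waves = []
    for i in range(n_waves):
        arc = np.full(n_frames, math.nan)
        t_end = merge_t[i] if merged[i] else frame_times_min[-1]
        sel = (frame_times_min >= t_birth[i]) & (frame_times_min <= t_end)
        arc[sel] = params.hillock_arc_um + speeds[i] * (frame_times_min[sel] - t_birth[i])
        arc[sel] = np.minimum(arc[sel], length[sel])
        waves.append(WaveRecord(
            inception_min=t_birth[i],
            speed_um_min=speeds[i],
            arc_um=arc,
            completed=merged[i],
            merge_min=merge_t[i],
            retraction_start_min=retr_start[i],
            retraction_amplitude_um=retr_amount[i] if retr_amount[i] > 0 else math.nan,
        ))

    soma_um = backbone.point(0.0)
    px = params.pixel_size_um
    wave0 = next((w for w in waves
                  if not math.isnan(w.arc_um[0]) and w.arc_um[0] > params.soma_radius_um),
                 None)
    def _px_point(p_um):
        return tuple(int(x) for x in np.round(p_um / px))

    seeds = {
        "soma": _px_point(soma_um),
        "hillock": _px_point(backbone.point(params.hillock_arc_um)),
        "edge": _px_point(backbone.point(length[0])),
        "wave": _px_point(backbone.point(wave0.arc_um[0])) if wave0 is not None else None,
    }
    return GroundTruth(
        times_s=frame_times_min * 60.0,
        length_um=length,
        gc_area_um2=area,
        waves=waves,
        soma_centroid_um=soma_um,
        pixel_size_um=px,
        backbone=backbone,
        seeds=seeds,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_scene(params: SimMovieParams, truth: GroundTruth, frame: int) -> np.ndarray:
    """Noise-free photon scene for one frame (background + structures)."""
    h, w = params.image_shape
    px = params.pixel_size_um
    scene = np.full((h, w), float(params.background_level))
    rr, cc = np.meshgrid(np.arange(h) * px, np.arange(w) * px, indexing="ij")

    # Soma: soft disc at the backbone origin.
    soma = truth.soma_centroid_um
    d_soma = np.hypot(rr - soma[0], cc - soma[1])
    scene += 0.8 * params.amplitude / (1.0 + np.exp((d_soma - params.soma_radius_um) / 0.5))

    # Neurite shaft + waves: distance/arc of every pixel to the occupied curve.
    L = truth.length_um[frame]
    keep = truth.backbone.s_um <= L
    curve = truth.backbone.points_um[keep]
    s_arc = truth.backbone.s_um[keep]
    tree = cKDTree(curve)
    reach = 3.5 * params.wave_lateral_sigma_um
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    dist, idx = tree.query(pix, distance_upper_bound=reach)
    near = np.isfinite(dist)
    d_um = dist[near]
    s_um = s_arc[np.minimum(idx[near], len(s_arc) - 1)]

    shaft_amp = 0.35 * params.amplitude
    vals = shaft_amp * np.exp(-(d_um**2) / (2 * params.shaft_sigma_um**2))
    for wave in truth.waves:
        s_w = wave.arc_um[frame]
        if math.isnan(s_w):
            continue
        env = np.exp(-((s_um - s_w) ** 2) / (2 * params.wave_sigma_um**2))
        lat = params.shaft_sigma_um + (params.wave_lateral_sigma_um - params.shaft_sigma_um) * env
        vals += params.amplitude * env * np.exp(-(d_um**2) / (2 * lat**2))
    flat = np.zeros(h * w)
    flat[near] = vals
    scene += flat.reshape(h, w)

    # Growth cone: soft disc at the tip whose pixel area equals the area state.
    tip = truth.backbone.point(L)
    r_gc = math.sqrt(truth.gc_area_um2[frame] / math.pi)
    d_tip = np.hypot(rr - tip[0], cc - tip[1])
    scene += params.amplitude / (1.0 + np.exp((d_tip - r_gc) / 0.3))
    return scene


def simulate_movie(params: SimMovieParams) -> tuple[CalibratedStack, GroundTruth]:
    """Render the full movie with shot + read noise; seeded and deterministic."""
    truth = simulate_dynamics(params)
    rng = np.random.default_rng((params.rng_seed, 1))
    frames = np.empty((params.n_frames, *params.image_shape))
    for f in range(params.n_frames):
        scene = render_scene(params, truth, f)
        noisy = rng.poisson(scene).astype(float)
        if params.read_noise_sd > 0:
            noisy += rng.normal(0.0, params.read_noise_sd, size=scene.shape)
        frames[f] = np.clip(noisy, 0.0, _MAX_INTENSITY)
    stack = CalibratedStack(frames=frames, pixel_size_um=params.pixel_size_um,
                            frame_interval_s=params.frame_interval_s)
    return stack, truth


def planted_pulling_events(truth: GroundTruth, min_amplitude_um: float = 5.0):
    """Observable retraction events implied by the ground-truth ledger.

    Waves arriving in quick succession chain their retractions into a single
    uninterrupted drop of the tip position; such overlapping per-wave
    retraction intervals are merged into one observable event.  Returns a
    list of ``(start_min, amplitude_um)`` computed from the recorded length
    series inside each merged interval.
    """
    t_min = truth.times_s / 60.0
    frame_dt = t_min[1] - t_min[0] if t_min.size > 1 else 0.0
    intervals = []
    for w in truth.waves:
        if not math.isfinite(w.retraction_start_min):
            continue
        end = w.merge_min if math.isfinite(w.merge_min) else t_min[-1]
        intervals.append((w.retraction_start_min, end))
    intervals.sort()
    merged: list[list[float]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1] + 2 * frame_dt:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    events = []
    for a, b in merged:
        i0 = int(np.searchsorted(t_min, a, side="right")) - 1
        i1 = min(int(np.searchsorted(t_min, b, side="left")) + 1, t_min.size - 1)
        i0 = max(i0, 0)
        amp = float(truth.length_um[i0] - truth.length_um[i0:i1 + 1].min())
        if amp >= min_amplitude_um:
            events.append((float(t_min[i0]), amp))
    return events


# ---------------------------------------------------------------------------
# STED scenes
# ---------------------------------------------------------------------------

ROI_LABELS = (
    "AW_central_rear", "AW_central_front", "AW_peripheral",
    "GC_central_transition", "GC_peripheral",
    "neurite_proximal", "neurite_distal",
)


@dataclass(frozen=True)
class RoiSpec:
    """A labelled polygonal region, vertices in pixel coordinates (row, col)."""

    label: str
    polygon_px: tuple  # ((r, c), ...)

    def shapely(self) -> Polygon:
        return Polygon([(c, r) for r, c in self.polygon_px])

    def area_um2(self, pixel_size_um: float) -> float:
        return self.shapely().area * pixel_size_um**2


@dataclass
class SimStedParams:
    """Conditions of one simulated two-channel STED still."""

    image_shape: tuple[int, int] = (640, 640)
    pixel_size_um: float = 0.025
    rois: tuple[RoiSpec, ...] = ()
    densities_per_um2: dict = field(default_factory=dict)  # label -> puncta/um^2
    actin_roi_means: dict = field(default_factory=dict)  # label -> mean intensity
    punctum_amplitude: float = 400.0
    punctum_sigma_um: float = 0.04
    min_diameter_nm: float = 40.0
    max_diameter_nm: float = 400.0
    background_level: float = 30.0
    actin_background: float = 60.0
    read_noise_sd: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0 or not self.punctum_sigma_um > 0:
            raise ValidationError("pixel_size_um/punctum_sigma_um: must be > 0")
        if any(d < 0 for d in self.densities_per_um2.values()):
            raise ValidationError("densities_per_um2: must be >= 0")
        polys = []
        for roi in self.rois:
            if roi.label not in ROI_LABELS:
                raise ValidationError(f"rois: unknown label {roi.label!r}")
            poly = roi.shapely()
            if not poly.is_valid or poly.area <= 0:
                raise GeometryError(f"rois: polygon for {roi.label!r} is not simple")
            polys.append((roi.label, poly))
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                la, pa = polys[i]
                lb, pb = polys[j]
                if la != lb and pa.intersection(pb).area > 1e-9:
                    raise GeometryError(
                        f"rois: {la!r} and {lb!r} overlap with conflicting labels")
        areas = {
            roi.label: roi.area_um2(self.pixel_size_um)
            for roi in self.rois if roi.label in ("neurite_proximal", "neurite_distal")
        }
        if len(areas) == 2:
            a, b = areas["neurite_proximal"], areas["neurite_distal"]
            if abs(a - b) > 0.05 * max(a, b):
                raise ValidationError("rois: proximal/distal sections must have equal areas")
            for v in (a, b):
                if not 8.0 <= v <= 12.0:
                    raise ValidationError(
                        "rois: proximal/distal sections must span 8-12 um^2")


def _sample_in_polygon(poly: Polygon, n: int, rng) -> np.ndarray:
    """Uniform points inside a polygon by rejection; returns (n, 2) (row, col) px."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        from shapely import contains_xy

        ok = contains_xy(poly, x, y)
        k = min(int(ok.sum()), n - got)
        sel = np.flatnonzero(ok)[:k]
        out[got:got + k, 0] = y[sel]  # row
        out[got:got + k, 1] = x[sel]  # col
        got += k
    return out


def _roi_mask(roi: RoiSpec, shape) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon

    verts = np.asarray(roi.polygon_px, dtype=float)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def simulate_sted_scene(params: SimStedParams):
    """Returns ``(image, truth_table, rois)``.

    ``image`` is ``(2, H, W)`` with channel 0 = actin, channel 1 = myosin;
    ``truth_table`` is a DataFrame with one planted punctum per row
    (``row_px``, ``col_px``, ``label``).
    """
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_shape
    sigma_px = params.punctum_sigma_um / params.pixel_size_um

    rows = []
    myosin = np.full((h, w), float(params.background_level))
    half = max(int(math.ceil(4 * sigma_px)), 2)
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    for roi in params.rois:
        density = params.densities_per_um2.get(roi.label, 0.0)
        area = roi.area_um2(params.pixel_size_um)
        n = int(rng.poisson(density * area))
        pts = _sample_in_polygon(roi.shapely(), n, rng)
        for r, c in pts:
            rows.append({"row_px": r, "col_px": c, "label": roi.label})
            ri, ci = int(round(r)), int(round(c))
            r0, r1 = max(ri - half, 0), min(ri + half + 1, h)
            c0, c1 = max(ci - half, 0), min(ci + half + 1, w)
            patch = params.punctum_amplitude * np.exp(
                -(((yy + ri - r) ** 2 + (xx + ci - c) ** 2)) / (2 * sigma_px**2))
            myosin[r0:r1, c0:c1] += patch[(r0 - ri + half):(r1 - ri + half),
                                          (c0 - ci + half):(c1 - ci + half)]

    # Actin channel: smooth filament texture plus per-ROI offsets that realise
    # the declared mean intensities.
    actin = np.full((h, w), float(params.actin_background))
    n_fil = 6
    rr_g, cc_g = np.mgrid[0:h, 0:w]
    for _ in range(n_fil):
        r0 = rng.uniform(0, h)
        slope = rng.uniform(-0.5, 0.5)
        dist = np.abs(rr_g - (r0 + slope * cc_g)) / math.sqrt(1 + slope**2)
        actin += 20.0 * np.exp(-(dist**2) / (2 * (3.0) ** 2))
    for roi in params.rois:
        target = params.actin_roi_means.get(roi.label)
        if target is None:
            continue
        mask = _roi_mask(roi, (h, w))
        if mask.any():
            actin[mask] += target - actin[mask].mean()
    actin = np.clip(actin, 0.0, None)

    image = np.empty((2, h, w))
    for ch, scene in enumerate((actin, myosin)):
        noisy = rng.poisson(scene).astype(float)
        if params.read_noise_sd > 0:
            noisy += rng.normal(0.0, params.read_noise_sd, size=scene.shape)
        image[ch] = np.clip(noisy, 0.0, _MAX_INTENSITY)

    truth = pd.DataFrame(rows, columns=["row_px", "col_px", "label"])
    return image, truth, list(params.rois)


# ---------------------------------------------------------------------------
# synthetic line-scan traces
# ---------------------------------------------------------------------------

def simulate_linescan_traces(
    n_traces: int,
    myosin_offset_um: float = 5.0,
    length_um: float = 60.0,
    step_um: float = 0.25,
    actin_sigma_um: float = 6.0,
    myosin_sigma_um: float = 5.0,
    noise_sd: float = 0.03,
    center_jitter_um: float = 5.0,
    rng_seed: int = 0,
):
    """Two-channel wave profiles with a planted actin-myosin peak offset.

    Arc positions increase toward the growth cone; the myosin peak sits
    ``myosin_offset_um`` behind (rear side of) the actin peak.  Each trace has
    a random arc shift and amplitude so that alignment and mean-normalization
    have real work to do.  Returns ``(positions_um, traces)`` where ``traces``
    is a list of ``(actin, myosin)`` arrays.
    """
    rng = np.random.default_rng(rng_seed)
    pos = np.arange(0.0, length_um + step_um / 2, step_um)
    traces = []
    for _ in range(n_traces):
        center = length_um * 0.55 + rng.uniform(-center_jitter_um, center_jitter_um)
        amp = rng.uniform(0.5, 2.0)
        actin = 0.1 + np.exp(-((pos - center) ** 2) / (2 * actin_sigma_um**2))
        myosin = 0.1 + np.exp(-((pos - (center - myosin_offset_um)) ** 2)
                              / (2 * myosin_sigma_um**2))
        actin = amp * (actin + rng.normal(0, noise_sd, pos.size))
        myosin = amp * (myosin + rng.normal(0, noise_sd, pos.size))
        traces.append((np.clip(actin, 0, None), np.clip(myosin, 0, None)))
    return pos, traces


# ---------------------------------------------------------------------------
# presets (the study conditions)
# ---------------------------------------------------------------------------

def movie_preset(name: str, rng_seed: int = 0, **overrides) -> SimMovieParams:
    """Named movie presets; ``paper-regime-20x`` is the default study regime."""
    if name == "paper-regime-20x":
        base = dict()
    elif name == "paper-regime-40x":
        base = dict(
            duration_min=15.0, frame_interval_s=7.5, pixel_size_um=0.16,
            image_shape=(256, 640), initial_length_um=50.0,
            gc_area_um2=40.0, wave_rate_per_h=6.0,
        )
    else:
        raise ValidationError(f"unknown movie preset {name!r}")
    base.update(overrides)
    return SimMovieParams(rng_seed=rng_seed, **base)


def _rect(r0, c0, dr, dc):
    return ((r0, c0), (r0, c0 + dc), (r0 + dr, c0 + dc), (r0 + dr, c0))


def sted_preset(name: str, rng_seed: int = 0, **overrides) -> SimStedParams:
    """Named STED presets with the study's regional density regime.

    ``sted-aw``: wave scene — central rear 8.2, central front 6.4, peripheral
    1.5, neurite sections 5.8 (proximal) vs 3.4 (distal) puncta/um^2.
    ``sted-gc``: growth-cone scene — central/transition 10.5 vs peripheral
    0.9 puncta/um^2.
    """
    px = 0.025
    # 10 um^2 rectangles: 4 x 2.5 um = 160 x 100 px.
    if name == "sted-aw":
        rois = (
            RoiSpec("AW_central_rear", _rect(220, 120, 100, 160)),
            RoiSpec("AW_central_front", _rect(220, 300, 100, 160)),
            RoiSpec("AW_peripheral", _rect(100, 120, 80, 340)),
            RoiSpec("neurite_proximal", _rect(360, 40, 100, 160)),
            RoiSpec("neurite_distal", _rect(360, 440, 100, 160)),
        )
        densities = {
            "AW_central_rear": 8.2, "AW_central_front": 6.4, "AW_peripheral": 1.5,
            "neurite_proximal": 5.8, "neurite_distal": 3.4,
        }
        actin = {
            "AW_central_rear": 500.0, "AW_central_front": 550.0, "AW_peripheral": 200.0,
            "neurite_proximal": 350.0, "neurite_distal": 300.0,
        }
    elif name == "sted-gc":
        rois = (
            RoiSpec("GC_central_transition", _rect(200, 150, 160, 200)),
            RoiSpec("GC_peripheral", _rect(200, 400, 160, 200)),
        )
        densities = {"GC_central_transition": 10.5, "GC_peripheral": 0.9}
        actin = {"GC_central_transition": 600.0, "GC_peripheral": 250.0}
    else:
        raise ValidationError(f"unknown STED preset {name!r}")
    base = dict(rois=rois, densities_per_um2=densities, actin_roi_means=actin,
                pixel_size_um=px)
    base.update(overrides)
    return SimStedParams(rng_seed=rng_seed, **base)


MOVIE_PRESETS = ("paper-regime-20x", "paper-regime-40x")
STED_PRESETS = ("sted-aw", "sted-gc")
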