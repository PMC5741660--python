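"""Wave kinematics: velocity, frequency, pulling events, elongation statistics.

Two distinct velocity notions coexist in actin-wave work and are kept as
separate operations here: the plain transit velocity (distance covered divided
by time taken, um/min) and the length-normalized transit rate (1/min), which
divides the reciprocal transit time by the fraction of the neurite covered.
Summaries default to the former; the two are reported side by side, never
mixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError
from .tracking import Trajectory

__all__ = [
    "WaveEvent",
    "KinematicsSummary",
    "PullingEvent",
    "wave_velocity",
    "normalized_transit_rate",
    "wave_frequency",
    "segment_wave_events",
    "detect_pulling_events",
    "elongation_vs_wave_count",
    "frequency_velocity_timecourse",
    "summarize",
]


@dataclass
class WaveEvent:
    """One wave's transit along the neurite."""

    start_frame: int
    end_frame: int
    start_min: float
    end_min: float
    distance_um: float
    duration_min: float
    velocity_um_min: float
    completed: bool
    retrograde: bool = False
    normalized_rate_per_min: float = math.nan

    def __post_init__(self) -> None:
        if not self.duration_min > 0:
            raise ValidationError("duration_min: must be > 0")


@dataclass
class PullingEvent:
    """A growth-cone retraction toward an approaching wave."""

    time_min: float         # onset of the retraction
    trough_min: float
    amplitude_um: float


@dataclass
class KinematicsSummary:
    frequency_per_h: float
    velocities_um_min: np.ndarray
    velocity_mean: float
    velocity_sem: float
    net_elongation_um: float
    pulling_events: list[PullingEvent] = field(default_factory=list)


def wave_velocity(times_min: np.ndarray, arc_um: np.ndarray) -> float:
    """Distance covered over time taken (um/min); negative = retrograde."""
    t = np.asarray(times_min, dtype=float)
    s = np.asarray(arc_um, dtype=float)
    ok = np.isfinite(t) & np.isfinite(s)
    t, s = t[ok], s[ok]
    if t.size < 2:
        raise InsufficientDataError("wave_velocity: needs >= 2 wave-present samples")
    dt = t[-1] - t[0]
    if not dt > 0:
        raise InsufficientDataError("wave_velocity: zero time span")
    return float((s[-1] - s[0]) / dt)


def normalized_transit_rate(event: WaveEvent, neurite_length_um: float) -> float:
    """(1 / transit time) x (distance covered / neurite length), 1/min.

    Returns NaN (not-applicable) for incomplete events.
    """
    if not neurite_length_um > 0:
        raise ValidationError("neurite_length_um: must be > 0")
    if not event.completed:
        return math.nan
    return (1.0 / event.duration_min) * (event.distance_um / neurite_length_um)


def wave_frequency(events: list[WaveEvent], span_h: float, complete_only: bool = False) -> float:
    """Events per hour over the observation span."""
    if not span_h > 0:
        raise ValidationError("span_h: must be > 0")
    n = sum(1 for e in events if e.completed or not complete_only)
    return n / span_h


def segment_wave_events(
    traj: Trajectory,
    *,
    backward_jump_um: float = 10.0,
    max_gap_frames: int = 2,
    completed_tol_um: float = 25.0,
    min_samples: int = 3,
) -> list[WaveEvent]:
    """Split the tracked wave series into per-wave events.

    The tracker follows the most distal wave; a backward jump larger than
    ``backward_jump_um`` (the leading wave merged, a trailing one takes over)
    or a presence gap longer than ``max_gap_frames`` starts a new event.  An
    event is complete when its last arc position ends within
    ``completed_tol_um`` of the neurite tip (the tip-exclusion band of the
    tracker plus the merge tolerance).
    """
    t_min = traj.times_s / 60.0
    idx = np.flatnonzero(traj.wave_present & np.isfinite(traj.wave_arc_um))
    events: list[WaveEvent] = []
    if idx.size == 0:
        return events
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        prev = runs[-1][-1]
        jump_back = traj.wave_arc_um[i] < traj.wave_arc_um[prev] - backward_jump_um
        if i - prev > max_gap_frames or jump_back:
            runs.append([int(i)])
        else:
            runs[-1].append(int(i))
    for run in runs:
        if len(run) < min_samples:
            continue
        fr = np.array(run)
        s = traj.wave_arc_um[fr]
        t = t_min[fr]
        v = wave_velocity(t, s)
        L_end = traj.length_um[fr[-1]]
        completed = bool(np.isfinite(L_end) and L_end - s[-1] <= completed_tol_um)
        events.append(WaveEvent(
            start_frame=int(fr[0]), end_frame=int(fr[-1]),
            start_min=float(t[0]), end_min=float(t[-1]),
            distance_um=float(s[-1] - s[0]), duration_min=float(t[-1] - t[0]),
            velocity_um_min=v, completed=completed, retrograde=v < 0,
        ))
    return events


def detect_pulling_events(
    times_min: np.ndarray,
    length_um: np.ndarray,
    wave_arc_um: np.ndarray,
    min_amplitude_um: float = 5.0,
    approach_window_um: float = 20.0,
) -> list[PullingEvent]:
    """Retraction events: a drop of L(t) that begins while a wave is close.

    A candidate is a drawdown of the length series: a running local peak
    followed by a decline of at least ``min_amplitude_um``, closed when the
    tip rebounds (rises more than a small hysteresis above the running
    trough) or the series ends.  Growth cycles may never regain the previous
    peak, so drawdowns are scanned locally rather than by global prominence.
    A candidate qualifies when, anywhere between its peak and its trough, a
    wave sits within ``approach_window_um`` of the tip, or a tracked wave
    disappears (merges with the growth cone) during the drop — fast
    retractions can complete within a single frame interval, leaving no
    sample with the wave still near the tip.  ``wave_arc_um`` may be a single
    series (the most distal tracked wave) or a ``(T, n_waves)`` matrix of
    per-wave arc positions.  An empty list is a legal result.
    """
    t = np.asarray(times_min, dtype=float)
    L = np.asarray(length_um, dtype=float)
    s = np.atleast_2d(np.asarray(wave_arc_um, dtype=float).T).T  # (T,) or (T, n_waves)
    if t.shape != L.shape or s.shape[0] != t.size:
        raise ValidationError("times/length/wave series must be aligned")
    ok = np.isfinite(L)
    if ok.sum() < 3:
        return []
    Lf = L.copy()
    Lf[~ok] = np.interp(t[~ok], t[ok], L[ok])
    hysteresis = 0.15 * min_amplitude_um

    events = []

    def close(peak_i, trough_i):
        amplitude = float(Lf[peak_i] - Lf[trough_i])
        if amplitude < min_amplitude_um:
            return
        a = max(peak_i - 1, 0)
        b = min(trough_i + 1, Lf.size - 1)
        gapd = Lf[a:b + 1, None] - s[a:b + 1]
        near = np.isfinite(gapd) & (np.abs(gapd) <= approach_window_um)
        fin = np.isfinite(s[a:b + 1])
        vanished = np.any(fin[:-1] & ~fin[1:]) if b > a else False
        if near.any() or vanished:
            events.append(PullingEvent(
                time_min=float(t[peak_i]), trough_min=float(t[trough_i]),
                amplitude_um=amplitude,
            ))

    peak_i = trough_i = 0
    for k in range(1, Lf.size):
        if Lf[peak_i] - Lf[trough_i] < min_amplitude_um and Lf[k] >= Lf[peak_i]:
            peak_i = trough_i = k          # new running high, no drawdown yet
        elif Lf[k] < Lf[trough_i]:
            trough_i = k                   # drawdown deepens
        elif Lf[k] > Lf[trough_i] + hysteresis:
            close(peak_i, trough_i)        # rebound closes the event
            peak_i = trough_i = k
    close(peak_i, trough_i)
    return events


def elongation_vs_wave_count(cohort: list[tuple[np.ndarray, int]]):
    """Net elongation vs wave count across a cohort, with Spearman rank rho.

    ``cohort``: one ``(length_um_series, wave_count)`` pair per neurite.
    Returns ``(table, rho, p)``; rho and p are NaN (undefined-correlation
    flag) when either variable is constant.
    """
    if len(cohort) < 3:
        raise InsufficientDataError("elongation_vs_wave_count: needs >= 3 neurites")
    rows = []
    for i, (L, count) in enumerate(cohort):
        L = np.asarray(L, dtype=float)
        ok = np.isfinite(L)
        rows.append({
            "neurite": i,
            "net_elongation_um": float(L[ok][-1] - L[ok][0]),
            "wave_count": int(count),
        })
    table = pd.DataFrame(rows)
    elong = table["net_elongation_um"].to_numpy()
    counts = table["wave_count"].to_numpy()
    if np.ptp(elong) == 0 or np.ptp(counts) == 0:
        return table, math.nan, math.nan
    rho, p = sps.spearmanr(counts, elong)
    return table, float(rho), float(p)


def frequency_velocity_timecourse(
    traj: Trajectory,
    events: list[WaveEvent],
    window_min: float = 60.0,
):
    """Windowed wave frequency vs tip velocity, plus their Pearson correlation.

    Non-overlapping windows of ``window_min``; per window the tip velocity is
    the length change over the window (um/min) and the frequency counts events
    begun inside it, scaled to per hour.  Returns a DataFrame and ``(r, p)``;
    the correlation is NaN-flagged when either series has zero variance.
    """
    t_min = traj.times_s / 60.0
    span = t_min[-1] - t_min[0]
    n_win = int(span // window_min)
    if n_win < 2:
        raise InsufficientDataError(
            f"frequency_velocity_timecourse: span {span:.1f} min < 2 windows")
    starts = t_min[0] + np.arange(n_win) * window_min
    freq = np.empty(n_win)
    vel = np.empty(n_win)
    L = traj.length_um
    ok = np.isfinite(L)
    for i, w0 in enumerate(starts):
        w1 = w0 + window_min
        freq[i] = sum(1 for e in events if w0 <= e.start_min < w1) / (window_min / 60.0)
        inside = ok & (t_min >= w0) & (t_min <= w1)
        ts, Ls = t_min[inside], L[inside]
        vel[i] = (Ls[-1] - Ls[0]) / (ts[-1] - ts[0]) if ts.size >= 2 else math.nan
    table = pd.DataFrame({
        "window_start_min": starts, "frequency_per_h": freq, "tip_velocity_um_min": vel})
    good = np.isfinite(vel)
    if good.sum() < 2 or np.ptp(freq[good]) == 0 or np.ptp(vel[good]) == 0:
        return table, math.nan, math.nan
    r, p = sps.pearsonr(freq[good], vel[good])
    return table, float(r), float(p)


def summarize(traj: Trajectory, events: list[WaveEvent],
              pulling: list[PullingEvent] | None = None) -> KinematicsSummary:
    """Per-neurite kinematics summary (mean +- SEM velocity, frequency, elongation)."""
    span_h = (traj.times_s[-1] - traj.times_s[0]) / 3600.0
    v = np.array([e.velocity_um_min for e in events])
    ok = np.isfinite(traj.length_um)
    L = traj.length_um[ok]
    return KinematicsSummary(
        frequency_per_h=wave_frequency(events, span_h) if span_h > 0 else math.nan,
        velocities_um_min=v,
        velocity_mean=float(v.mean()) if v.size else math.nan,
        velocity_sem=float(v.std(ddof=1) / math.sqrt(v.size)) if v.size >= 2 else math.nan,
        net_elongation_um=float(L[-1] - L[0]) if L.size else math.nan,
        pulling_events=pulling or [],
    )
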