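"""Wave velocity/frequency, pulling events, elongation and time-course stats."""

import math

import numpy as np
import pytest

from wavetrack.errors import InsufficientDataError
from wavetrack.kinematics import (WaveEvent, detect_pulling_events,
                                  elongation_vs_wave_count,
                                  frequency_velocity_timecourse,
                                  normalized_transit_rate, segment_wave_events,
                                  wave_frequency, wave_velocity)
from wavetrack.tracking import Trajectory


def _make_traj(t_min, L, s, present=None):
    t_min = np.asarray(t_min, dtype=float)
    n = t_min.size
    if present is None:
        present = np.isfinite(np.asarray(s, dtype=float))
    return Trajectory(
        times_s=t_min * 60.0,
        soma_rc=np.zeros((n, 2)), hillock_rc=np.zeros((n, 2)),
        edge_rc=np.zeros((n, 2)),
        length_um=np.asarray(L, dtype=float),
        wave_arc_um=np.asarray(s, dtype=float),
        wave_present=np.asarray(present, dtype=bool),
        gap=np.zeros(n, dtype=bool), pixel_size_um=0.65)


class TestWaveVelocity:
    def test_distance_over_time(self):
        assert wave_velocity([0, 4, 8], [10, 20, 30]) == pytest.approx(2.5)

    def test_constant_position_is_zero(self):
        assert wave_velocity([0, 5, 10], [12, 12, 12]) == 0.0

    def test_retrograde_is_negative(self):
        assert wave_velocity([0, 10], [30, 10]) == pytest.approx(-2.0)

    def test_time_shift_and_resampling_invariance(self):
        t = np.linspace(0, 8, 5)
        s = 10 + 2.5 * t
        v0 = wave_velocity(t, s)
        assert wave_velocity(t + 137.0, s) == pytest.approx(v0)
        t_fine = np.linspace(0, 8, 81)
        assert wave_velocity(t_fine, 10 + 2.5 * t_fine) == pytest.approx(v0)

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientDataError):
            wave_velocity([3.0], [10.0])


class TestNormalizedTransitRate:
    def _event(self, distance, duration, completed=True):
        return WaveEvent(start_frame=0, end_frame=1, start_min=0.0,
                         end_min=duration, distance_um=distance,
                         duration_min=duration,
                         velocity_um_min=distance / duration, completed=completed)

    def test_full_transit(self):
        ev = self._event(100.0, 40.0)
        assert normalized_transit_rate(ev, 100.0) == pytest.approx(0.025)

    def test_half_length_transit(self):
        ev = self._event(50.0, 40.0)
        assert normalized_transit_rate(ev, 100.0) == pytest.approx(0.0125)

    def test_equals_velocity_over_length_for_full_transit(self):
        ev = self._event(80.0, 25.0)
        assert normalized_transit_rate(ev, 80.0) == pytest.approx(
            ev.velocity_um_min / 80.0)

    def test_incomplete_flagged_nan(self):
        ev = self._event(30.0, 10.0, completed=False)
        assert math.isnan(normalized_transit_rate(ev, 100.0))


class TestWaveFrequency:
    def _events(self, n, n_complete):
        out = []
        for i in range(n):
            out.append(WaveEvent(
                start_frame=i, end_frame=i + 1, start_min=float(i),
                end_min=i + 1.0, distance_um=10.0, duration_min=1.0,
                velocity_um_min=10.0, completed=i < n_complete))
        return out

    def test_events_per_hour(self):
        assert wave_frequency(self._events(6, 6), 2.0) == pytest.approx(3.0)

    def test_complete_only(self):
        assert wave_frequency(self._events(6, 4), 2.0, complete_only=True) \
            == pytest.approx(2.0)


class TestSegmentWaveEvents:
    def test_backward_jump_starts_new_event(self):
        t = np.arange(20.0) * 2
        s = np.concatenate([10 + 2.0 * t[:10], 5 + 2.0 * (t[:10])])
        L = np.full(20, 120.0)
        traj = _make_traj(t, L, s)
        events = segment_wave_events(traj, min_samples=3)
        assert len(events) == 2
        for ev in events:
            assert ev.velocity_um_min == pytest.approx(2.0)

    def test_no_wave_frames_give_no_events(self):
        t = np.arange(10.0)
        traj = _make_traj(t, np.full(10, 100.0), np.full(10, np.nan))
        assert segment_wave_events(traj) == []


class TestDetectPullingEvents:
    def test_planted_retraction_detected_with_amplitude(self):
        t = np.arange(0, 120, 2.0)
        L = np.full(t.size, 100.0)
        L[30:36] = 100 - np.linspace(0, 15, 6)
        L[36:] = 85 + 0.5 * (t[36:] - t[36])
        s = np.where((t > 40) & (t < 75), np.nan, np.nan)
        s[25:36] = 70 + 2.0 * (t[25:36] - t[25])  # approaches the tip
        events = detect_pulling_events(t, L, s, min_amplitude_um=5.0)
        assert len(events) == 1
        assert events[0].amplitude_um == pytest.approx(15.0, rel=0.05)

    def test_monotone_growth_no_waves_empty(self):
        t = np.arange(0, 100, 2.0)
        events = detect_pulling_events(t, 50 + 0.9 * t, np.full(t.size, np.nan))
        assert events == []

    def test_subthreshold_retraction_ignored(self):
        t = np.arange(0, 60, 2.0)
        L = np.full(t.size, 100.0)
        L[10:15] -= np.linspace(0, 2.0, 5)  # 2 um dip
        s = np.full(t.size, np.nan)
        s[8:15] = 90.0
        assert detect_pulling_events(t, L, s, min_amplitude_um=5.0) == []

    def test_drop_without_nearby_wave_ignored(self):
        t = np.arange(0, 60, 2.0)
        L = np.full(t.size, 100.0)
        L[10:20] = 100 - np.linspace(0, 20, 10)
        s = np.full(t.size, np.nan)
        s[5:25] = 20.0  # wave far from the tip the whole time
        assert detect_pulling_events(t, L, s, min_amplitude_um=5.0) == []


class TestElongationVsWaveCount:
    def test_planted_monotone_relation(self, rng):
        cohort = []
        for count in range(20):
            elong = 400 - 20 * count + rng.normal(0, 5)
            L = np.array([50.0, 50.0 + elong])
            cohort.append((L, count))
        _, rho, p = elongation_vs_wave_count(cohort)
        assert rho < -0.9
        assert p < 0.01

    def test_identical_elongations_flagged(self):
        cohort = [(np.array([50.0, 80.0]), c) for c in (1, 5, 9)]
        _, rho, p = elongation_vs_wave_count(cohort)
        assert math.isnan(rho) and math.isnan(p)

    def test_needs_three_neurites(self):
        with pytest.raises(InsufficientDataError):
            elongation_vs_wave_count([(np.array([0.0, 1.0]), 1)] * 2)


class TestFrequencyVelocityTimecourse:
    def _alternating_traj(self):
        """1 h fast wave-free epochs alternating with 1 h slow wave-rich ones."""
        dt = 2.0
        t = np.arange(0, 480, dt)
        L = np.zeros(t.size)
        events = []
        cur = 100.0
        for i, ti in enumerate(t):
            hour = int(ti // 60)
            fast = hour % 2 == 0
            cur += (2.5 if fast else 0.5) * dt
            L[i] = cur
        for hour in range(8):
            if hour % 2 == 1:
                for k in range(3):
                    start = hour * 60 + 5 + 18 * k
                    events.append(WaveEvent(
                        start_frame=int(start / dt), end_frame=int(start / dt) + 5,
                        start_min=start, end_min=start + 10, distance_um=20.0,
                        duration_min=10.0, velocity_um_min=2.0, completed=True))
        traj = _make_traj(t, L, np.full(t.size, np.nan))
        return traj, events

    def test_planted_alternation_anticorrelates(self):
        traj, events = self._alternating_traj()
        table, r, p = frequency_velocity_timecourse(traj, events, window_min=60.0)
        assert r < -0.5

    def test_constant_growth_no_waves(self):
        t = np.arange(0, 240, 2.0)
        traj = _make_traj(t, 50 + 1.0 * t, np.full(t.size, np.nan))
        table, r, p = frequency_velocity_timecourse(traj, [], window_min=60.0)
        assert np.all(table["frequency_per_h"] == 0)
        assert np.allclose(table["tip_velocity_um_min"], 1.0)
        assert math.isnan(r)  # zero-variance frequency flagged

    def test_window_longer_than_movie(self):
        t = np.arange(0, 30, 2.0)
        traj = _make_traj(t, 50 + t, np.full(t.size, np.nan))
        with pytest.raises(InsufficientDataError):
            frequency_velocity_timecourse(traj, [], window_min=60.0)
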