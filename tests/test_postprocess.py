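"""Thresholding, event filtering, sleep-time estimation, AHI, severity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capnea.postprocess import (
    QuietConfig,
    ThresholdConfig,
    classify_severity,
    compute_ahi,
    detect_quiet_segments,
    estimate_sleep_time,
    filter_short_events,
    run_pipeline,
    threshold_probabilities,
)
from capnea.recording import EventInterval, EventIntervalSet, Recording


class TestThresholdProbabilities:
    def test_at_least_equal_is_inclusive(self):
        out = threshold_probabilities(np.array([0.2, 0.5, 0.7]), 0.5)
        np.testing.assert_array_equal(out, [0, 1, 1])

    def test_extremes(self):
        p = np.array([0.1, 0.9])
        assert threshold_probabilities(p, 0.0).all()
        assert not threshold_probabilities(p, 0.95).any()

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_antitone_in_theta(self, t1, t2):
        lo, hi = sorted([t1, t2])
        p = np.linspace(0, 1, 37)
        assert np.all(
            threshold_probabilities(p, hi) <= threshold_probabilities(p, lo)
        )


class TestFilterShortEvents:
    def test_ten_second_minimum_at_tau_50(self):
        events = EventIntervalSet([
            EventInterval(0.0, 9.8),    # 49 samples at 5 Hz
            EventInterval(20.0, 30.0),  # 50 samples = 10 s
        ])
        kept = filter_short_events(events, tau=50, sample_rate=5.0)
        assert len(kept) == 1
        assert kept[0].start == 20.0

    def test_empty_and_idempotent(self):
        assert len(filter_short_events(EventIntervalSet(), 50, 5.0)) == 0
        events = EventIntervalSet([EventInterval(0, 12), EventInterval(20, 25)])
        once = filter_short_events(events, 50, 5.0)
        twice = filter_short_events(once, 50, 5.0)
        assert once == twice

    @given(st.integers(1, 120))
    def test_count_nonincreasing_in_tau(self, tau):
        events = EventIntervalSet(
            [EventInterval(10 * i, 10 * i + d) for i, d in
             enumerate([3, 5, 8, 10, 12, 20, 24])]
        )
        kept = filter_short_events(events, tau, 5.0)
        kept_stricter = filter_short_events(events, tau + 10, 5.0)
        assert len(kept_stricter) <= len(kept) <= len(events)
        assert all(iv in list(events) for iv in kept)


class TestQuietSegments:
    def test_constant_1g_all_quiet(self):
        quiet = detect_quiet_segments(np.ones(1500), QuietConfig(), 5.0)
        assert quiet.all()

    def test_single_burst_sample_breaks_epoch(self):
        x = np.ones(1500)
        x[200] = 1.5
        quiet = detect_quiet_segments(x, QuietConfig(), 5.0)
        assert not quiet[1] and quiet[0] and quiet[2:].all()

    def test_within_bounds(self):
        quiet = detect_quiet_segments(np.full(300, 1.05), QuietConfig(), 5.0)
        assert quiet.all()


def _acti_recording(duration_min, move_start_min=0.0, move_end_min=0.0, fs=5.0):
    """Supine night with movement at the start/end of the recording."""
    n = int(duration_min * 60 * fs)
    t = np.arange(n) / fs
    acc_z = np.full(n, -1.0)
    acc_x = np.zeros(n)
    acc_y = np.zeros(n)
    move = np.zeros(n, dtype=bool)
    move[: int(move_start_min * 60 * fs)] = True
    if move_end_min > 0:
        move[-int(move_end_min * 60 * fs):] = True
    acc_x[move] = 0.8 * np.sign(np.sin(np.arange(move.sum())))  # |a| ≈ 1.28
    return Recording(t=t, cap=np.sin(t), acc_x=acc_x, acc_y=acc_y,
                     acc_z=acc_z, sample_rate=fs)


class TestEstimateSleepTime:
    def test_latency_wake_and_st(self):
        rec = _acti_recording(400.0, move_start_min=30.0, move_end_min=10.0)
        positions = np.ones(rec.n_samples, dtype=int)  # supine
        s = estimate_sleep_time(rec, positions)
        assert s.sleep_latency == pytest.approx(30.0)
        assert s.morning_wake == pytest.approx(10.0)
        assert s.sleep_time == pytest.approx(360.0)

    def test_quiet_from_first_sample(self):
        rec = _acti_recording(60.0)
        s = estimate_sleep_time(rec, np.ones(rec.n_samples, dtype=int))
        assert s.sleep_latency == 0.0

    def test_upright_time_reduces_st(self):
        rec = _acti_recording(400.0, move_start_min=30.0, move_end_min=10.0)
        positions = np.ones(rec.n_samples, dtype=int)
        i0 = int(100 * 60 * rec.sample_rate)
        i1 = int(120 * 60 * rec.sample_rate)
        positions[i0:i1] = 0  # 20 min upright mid-night
        s = estimate_sleep_time(rec, positions)
        assert s.upright_time == pytest.approx(20.0)
        assert s.sleep_time == pytest.approx(340.0)

    def test_bookkeeping_closes(self):
        rec = _acti_recording(200.0, move_start_min=15.0, move_end_min=20.0)
        s = estimate_sleep_time(rec, np.ones(rec.n_samples, dtype=int))
        total = s.sleep_time + s.sleep_latency + s.morning_wake + s.upright_time
        assert total == pytest.approx(rec.duration_minutes)

    def test_no_sleep_onset_raises(self):
        rec = _acti_recording(30.0, move_start_min=30.0)
        with pytest.raises(ValueError, match="no sleep onset"):
            estimate_sleep_time(rec, np.ones(rec.n_samples, dtype=int))


class TestComputeAhi:
    def test_worked_example(self):
        assert compute_ahi(290, 384.6) == 45.2

    def test_zero_events(self):
        assert compute_ahi(0, 300.0) == 0.0

    def test_ten_per_two_hours(self):
        assert compute_ahi(10, 120.0) == 5.0

    def test_scale_consistency(self):
        assert compute_ahi(40, 200.0) == compute_ahi(80, 400.0)

    def test_zero_sleep_time_raises(self):
        with pytest.raises(ValueError, match="positive"):
            compute_ahi(5, 0.0)


class TestSeverity:
    @pytest.mark.parametrize("ahi,band", [
        (4.9, "normal"), (5.0, "mild"), (14.9, "mild"),
        (15.0, "moderate"), (29.9, "moderate"), (30.0, "severe"),
        (45.2, "severe"), (0.0, "normal"),
    ])
    def test_bands(self, ahi, band):
        assert classify_severity(ahi) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(-1.0)


class _StubModel:
    """Deterministic probability emitter for pipeline plumbing tests."""

    def __init__(self, prob_fn):
        self.prob_fn = prob_fn

    def forward(self, X, train=False, rng=None):
        B, P, _ = X.shape
        return self.prob_fn(B, P), None


class TestRunPipeline:
    def test_zero_probability_night_is_normal(self):
        rec = _acti_recording(120.0, move_start_min=15.0, move_end_min=10.0)
        model = _StubModel(lambda B, P: np.full((B, P), 0.01))
        summary, events = run_pipeline(rec, model,
                                       ThresholdConfig(theta_p=0.5, tau=50))
        assert summary.n_events == 0
        assert summary.ahi == 0.0
        assert summary.severity == "normal"
        assert len(events) == 0

    def test_reported_count_matches_filtered_events(self):
        rec = _acti_recording(120.0, move_start_min=15.0, move_end_min=10.0)
        rng = np.random.default_rng(8)

        def prob_fn(B, P):
            return rng.random((B, P))  # speckle: mostly sub-10 s detections

        summary, events = run_pipeline(
            rec, _StubModel(prob_fn), ThresholdConfig(theta_p=0.6, tau=50)
        )
        assert summary.n_events == len(events)
        assert all(iv.duration >= 10.0 for iv in events)
        sleep_lo = summary.sleep_latency * 60.0
        sleep_hi = (rec.duration_minutes - summary.morning_wake) * 60.0
        for iv in events:
            assert iv.start >= sleep_lo and iv.end <= sleep_hi
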