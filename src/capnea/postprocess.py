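"""From per-sample probabilities to events, sleep time, AHI and severity.

The detection pipeline ends with two thresholds and an actigraphy step:

* θp — the apnea-probability threshold.  A sample is apnea iff p ≥ θp
  (θp is normally chosen by the Youden index on validation data, see
  :mod:`capnea.agreement`).
* τ — the event time threshold, in samples.  Predicted apnea intervals
  shorter than τ are discarded; at 5 Hz, τ = 50 removes intervals shorter
  than the 10-s minimum duration of a scoreable event.
* Sleep time (ST) from the acceleration-vector length: the night is split
  into epochs; an epoch is movement-free iff every acceleration-length
  sample lies within pre-defined bounds around 1 g.  Sleep onset is the
  start of the first movement-free run of at least 10 min; the morning
  wake-up period is found by running the identical rule on the
  time-reversed series.  Awake time = sleep latency + morning wake +
  upright-position time within the sleep interval, and
  ST = recording duration − awake time.

AHI = 60 × (number of detected events) / ST (minutes), reported to one
decimal, with severity bands: normal < 5 ≤ mild < 15 ≤ moderate < 30 ≤
severe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureConfig, build_features, POSITION_UPRIGHT
from .models import predict_night
from .recording import EventInterval, EventIntervalSet, Recording, events_from_labels

__all__ = [
    "ThresholdConfig",
    "QuietConfig",
    "SleepSummary",
    "SEVERITY_BANDS",
    "threshold_probabilities",
    "filter_short_events",
    "detect_quiet_segments",
    "estimate_sleep_time",
    "compute_ahi",
    "classify_severity",
    "run_pipeline",
]

SEVERITY_BANDS = (("normal", 0.0), ("mild", 5.0), ("moderate", 15.0), ("severe", 30.0))


@dataclass(frozen=True)
class ThresholdConfig:
    """Detection thresholds: θp on probability, τ on event length."""

    theta_p: float = 0.5
    tau: int = 50              # samples; 10 s at 5 Hz
    sample_rate: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_p <= 1.0:
            raise ValueError("theta_p must lie in [0, 1]")
        if self.tau < 1:
            raise ValueError("tau must be at least one sample")


@dataclass(frozen=True)
class QuietConfig:
    """Movement detection for sleep-time estimation.

    The bounds bracket 1 g so that a still body (gravity only, plus sensor
    noise) is "quiet" while movement excursions are not; they are
    device-calibration constants, configurable.
    """

    epoch: float = 30.0          # seconds
    lower: float = 0.9           # g
    upper: float = 1.1           # g
    min_quiet_run: float = 10.0  # minutes

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.min_quiet_run <= 0 or self.epoch <= 0:
            raise ValueError("epoch and min_quiet_run must be positive")


@dataclass
class SleepSummary:
    """Night-level summary; all durations in minutes."""

    sleep_latency: float
    morning_wake: float
    upright_time: float
    sleep_time: float
    n_events: int = 0
    ahi: float = 0.0
    severity: str = "normal"

    def to_dict(self) -> dict:
        return {
            "sleep_latency_min": self.sleep_latency,
            "morning_wake_min": self.morning_wake,
            "upright_time_min": self.upright_time,
            "sleep_time_min": self.sleep_time,
            "n_events": self.n_events,
            "ahi": self.ahi,
            "severity": self.severity,
        }


def threshold_probabilities(p: np.ndarray, theta_p: float) -> np.ndarray:
    """Binary apnea labels: 1 iff p ≥ θp ("at least equal")."""
    if not 0.0 <= theta_p <= 1.0:
        raise ValueError("theta_p must lie in [0, 1]")
    return (np.asarray(p) >= theta_p).astype(np.int8)


def filter_short_events(events: EventIntervalSet, tau: int,
                        sample_rate: float) -> EventIntervalSet:
    """Drop predicted intervals shorter than τ samples; idempotent.

    With τ = 50 at 5 Hz this removes intervals shorter than 10 s, the
    minimum duration of a scoreable apnea.  Surviving events are untouched.
    """
    min_seconds = tau / sample_rate
    return EventIntervalSet(
        iv for iv in events if iv.duration >= min_seconds - 1e-9
    )


def detect_quiet_segments(acc_len: np.ndarray, qc: QuietConfig = QuietConfig(),
                          sample_rate: float = 5.0) -> np.ndarray:
    """Boolean per-epoch series: True iff the epoch has no body movement.

    The recording is partitioned into consecutive epochs (a trailing partial
    epoch counts as one); an epoch is quiet iff *every* acceleration-length
    sample within it lies inside ``[lower, upper]``.
    """
    x = np.asarray(acc_len, dtype=float)
    eps = max(1, int(round(qc.epoch * sample_rate)))
    n_epochs = int(np.ceil(x.size / eps))
    quiet = np.empty(n_epochs, dtype=bool)
    for k in range(n_epochs):
        seg = x[k * eps:(k + 1) * eps]
        quiet[k] = bool(np.all((seg >= qc.lower) & (seg <= qc.upper)))
    return quiet


def _first_long_quiet_run(quiet: np.ndarray, min_epochs: int) -> int | None:
    """Index of the first epoch starting a quiet run of >= min_epochs."""
    run = 0
    for k, q in enumerate(quiet):
        run = run + 1 if q else 0
        if run >= min_epochs:
            return k - min_epochs + 1
    return None


def estimate_sleep_time(rec: Recording, positions: np.ndarray,
                        qc: QuietConfig = QuietConfig()) -> SleepSummary:
    """Actigraphy-style sleep bookkeeping from the acceleration channels.

    Returns a :class:`SleepSummary` with event fields zeroed; raises
    ``ValueError`` when no movement-free run of ``min_quiet_run`` exists
    (no sleep onset found).
    """
    from .features import accel_length

    acc_len = np.asarray(accel_length(rec.acc_x, rec.acc_y, rec.acc_z))
    quiet = detect_quiet_segments(acc_len, qc, rec.sample_rate)
    min_epochs = int(np.ceil(qc.min_quiet_run * 60.0 / qc.epoch))
    onset_epoch = _first_long_quiet_run(quiet, min_epochs)
    if onset_epoch is None:
        raise ValueError("no sleep onset found: no movement-free run of "
                         f"{qc.min_quiet_run} min")
    wake_epoch_rev = _first_long_quiet_run(quiet[::-1], min_epochs)
    # onset exists, so the reversed scan must find a run too
    assert wake_epoch_rev is not None
    latency_min = onset_epoch * qc.epoch / 60.0
    morning_wake_min = wake_epoch_rev * qc.epoch / 60.0

    duration_min = rec.duration_minutes
    sleep_lo = latency_min * 60.0
    sleep_hi = (duration_min - morning_wake_min) * 60.0
    in_sleep = (rec.t >= sleep_lo) & (rec.t < sleep_hi)
    upright_min = float(np.sum(in_sleep & (np.asarray(positions) ==
                                           POSITION_UPRIGHT))) / rec.sample_rate / 60.0
    st = duration_min - latency_min - morning_wake_min - upright_min
    if st <= 0:
        raise ValueError("estimated awake time exhausts the recording")
    return SleepSummary(
        sleep_latency=latency_min,
        morning_wake=morning_wake_min,
        upright_time=upright_min,
        sleep_time=st,
    )


def compute_ahi(n_events: int, st_minutes: float) -> float:
    """Apnea–hypopnea index: 60 × events / ST, to one decimal."""
    if st_minutes <= 0:
        raise ValueError("sleep time must be positive")
    return round(60.0 * n_events / st_minutes, 1)


def classify_severity(ahi: float) -> str:
    """Severity band: normal < 5 ≤ mild < 15 ≤ moderate < 30 ≤ severe."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    label = "normal"
    for name, lo in SEVERITY_BANDS:
        if ahi >= lo:
            label = name
    return label


def run_pipeline(
    rec: Recording,
    model,
    tcfg: ThresholdConfig = ThresholdConfig(),
    qc: QuietConfig = QuietConfig(),
    feature_config: FeatureConfig | None = None,
) -> tuple[SleepSummary, EventIntervalSet]:
    """Whole-night detection: features → p → θp/τ thresholds → ST → AHI.

    Predicted events are restricted (clipped) to the estimated sleep
    interval before the τ filter, so wake-time false positives never count
    toward the AHI.
    """
    frame = build_features(rec, feature_config)
    probs = predict_night(model, frame)
    summary = estimate_sleep_time(rec, frame.position_code, qc)
    labels = threshold_probabilities(probs, tcfg.theta_p)
    events = events_from_labels(labels, rec.sample_rate, t0=rec.t[0])
    sleep_lo = summary.sleep_latency * 60.0
    sleep_hi = (rec.duration_minutes - summary.morning_wake) * 60.0
    events = events.clip(sleep_lo, sleep_hi)
    events = filter_short_events(events, tcfg.tau, tcfg.sample_rate)
    summary.n_events = len(events)
    summary.ahi = compute_ahi(len(events), summary.sleep_time)
    summary.severity = classify_severity(summary.ahi)
    return summary, events
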