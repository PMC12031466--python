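"""Simulated overnight recordings with known ground truth.

No recording cohort is publicly deposited for this device, so every
downstream stage is exercised on simulated nights.  The generator emulates
the signal structure the detection pipeline relies on:

* a quasi-periodic capacitance oscillation at an instantaneous respiratory
  rate near 15 breaths/min (bounded random walk in 0–30 breaths/min), on a
  slowly drifting baseline, with additive Gaussian sensor noise;
* apnea/hypopnea episodes of at least 10 s during which the oscillation
  amplitude is multiplied by a suppression factor (near-total collapse for
  apneas, partial for hypopneas), with onsets from a homogeneous Poisson
  process at the target AHI per sleep-hour and non-overlap enforced;
* an accelerometer reading the gravity vector of the scheduled body
  position plus noise, with high-variance movement throughout the wake
  segments at the start and end of the night and short movement bursts
  during sleep;
* ground truth for events, per-sample position, sleep latency, morning
  wake, upright time, total sleep time, and the realized AHI.

Identical seeds produce bit-identical nights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .recording import EventInterval, EventIntervalSet, Recording
from .features import POSITION_NAMES

__all__ = [
    "SimConfig",
    "TruthSleep",
    "SimulatedNight",
    "PerturbationSpec",
    "simulate_night",
    "simulate_paired_devices",
    "simulate_cohort",
]

#: Gravity direction (in g) for each position code.
_GRAVITY = {
    0: (1.0, 0.0, 0.0),    # upright: x-axis along gravity
    1: (0.0, 0.0, -1.0),   # supine
    2: (0.0, 0.0, 1.0),    # prone
    3: (0.0, -1.0, 0.0),   # left
    4: (0.0, 1.0, 0.0),    # right
}


@dataclass(frozen=True)
class SimConfig:
    """Stated world for one simulated night.

    Defaults encode the device protocol (5 Hz sampling), the scoring rules
    (events last at least 10 s) and the breathing-rate assumption
    (15 breaths/min nominal, 0–30 during disturbed breathing).  Amplitudes
    and noise levels are stated assumptions: breathing amplitude is 1
    capacitance unit with sensor noise SD 0.1 (per-breath SNR ≈ 10), apneas
    suppress the oscillation to 5 % of its amplitude and hypopneas to 50 %.
    """

    duration: float = 420.0              # minutes
    sample_rate: float = 5.0             # Hz
    target_ahi: float = 15.0             # events per sleep-hour (Poisson rate)
    mean_resp_rate: float = 15.0         # breaths/min
    resp_rate_range: tuple[float, float] = (0.0, 30.0)
    event_duration_range: tuple[float, float] = (10.0, 60.0)   # seconds
    hypopnea_fraction: float = 0.3
    apnea_suppression: float = 0.05      # fractional amplitude during apnea
    hypopnea_suppression: float = 0.5
    sleep_latency: float = 20.0          # minutes of wakefulness at start
    morning_wake: float = 10.0           # minutes of wakefulness at end
    position_schedule: tuple[tuple[float, str], ...] = ((0.0, "supine"),)
    movement_burst_rate: float = 2.0     # bursts per sleep-hour
    noise_sd: float = 0.1                # capacitance units
    acc_noise_sd: float = 0.02           # g, per axis, quiet sleep
    movement_sd: float = 0.3             # g, per axis, during wake/bursts
    breathing_amplitude: float = 1.0     # capacitance units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= self.sleep_latency + self.morning_wake:
            raise ValueError("duration must exceed sleep_latency + morning_wake")
        if self.event_duration_range[0] < 10.0:
            raise ValueError("apnea events must last at least 10 s")
        if self.event_duration_range[1] < self.event_duration_range[0]:
            raise ValueError("event_duration_range must be nondecreasing")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be non-negative")
        if not 0.0 <= self.hypopnea_fraction <= 1.0:
            raise ValueError("hypopnea_fraction must lie in [0, 1]")
        for _, pos in self.position_schedule:
            if pos not in POSITION_NAMES:
                raise ValueError(f"unknown position {pos!r}")


@dataclass(frozen=True)
class TruthSleep:
    """Ground-truth sleep bookkeeping, all durations in minutes."""

    sleep_latency: float
    morning_wake: float
    upright_time: float
    sleep_time: float
    n_events: int
    ahi: float


@dataclass
class SimulatedNight:
    recording: Recording
    truth_events: EventIntervalSet
    truth_sleep: TruthSleep
    truth_positions: np.ndarray


@dataclass(frozen=True)
class PerturbationSpec:
    """How a simulated reference device mis-scores the truth events."""

    onset_jitter_sd: float = 0.0     # seconds
    duration_jitter_sd: float = 0.0  # seconds
    drop_prob: float = 0.0
    insert_rate: float = 0.0         # spurious events per hour


def _position_track(cfg: SimConfig, n: int) -> np.ndarray:
    """Per-sample position codes from the (start-minute, name) schedule."""
    codes = np.zeros(n, dtype=np.int8)
    sched = sorted(cfg.position_schedule)
    if not sched or sched[0][0] > 0:
        sched = [(0.0, "supine")] + list(sched)
    for start_min, name in sched:
        i0 = int(round(start_min * 60 * cfg.sample_rate))
        codes[min(i0, n):] = POSITION_NAMES.index(name)
    return codes


def _draw_events(cfg: SimConfig, rng: np.random.Generator,
                 sleep_start: float, sleep_end: float,
                 upright_mask_fn) -> EventIntervalSet:
    """Poisson number of non-overlapping events inside the sleep interval."""
    st_hours = (sleep_end - sleep_start) / 3600.0
    n_ev = int(rng.poisson(cfg.target_ahi * st_hours))
    if n_ev == 0:
        return EventIntervalSet()
    placed: list[tuple[float, float, str]] = []
    guard = 2.0  # seconds between consecutive events
    tries = 0
    max_tries = 200 * n_ev + 1000
    while len(placed) < n_ev:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_ev} non-overlapping events in "
                f"{st_hours:.2f} h of sleep; lower target_ahi"
            )
        dur = rng.uniform(*cfg.event_duration_range)
        start = rng.uniform(sleep_start, sleep_end - dur)
        end = start + dur
        if upright_mask_fn(start, end):
            continue
        if any(start < e + guard and end + guard > s for s, e, _ in placed):
            continue
        if rng.random() < cfg.hypopnea_fraction:
            etype = "hypopnea"
        else:
            etype = rng.choice(
                ["obstructive", "central", "mixed"], p=[0.8, 0.15, 0.05]
            )
        placed.append((start, end, str(etype)))
    return EventIntervalSet(EventInterval(s, e, ty) for s, e, ty in placed)


def simulate_night(cfg: SimConfig) -> SimulatedNight:
    """Generate one night; deterministic for a fixed :class:`SimConfig`."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.duration * 60 * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    sleep_start = cfg.sleep_latency * 60.0
    sleep_end = (cfg.duration - cfg.morning_wake) * 60.0

    positions = _position_track(cfg, n)
    upright = positions == 0
    in_sleep = (t >= sleep_start) & (t < sleep_end)
    upright_sleep_min = float(np.sum(upright & in_sleep)) / fs / 60.0
    sleep_time_min = (sleep_end - sleep_start) / 60.0 - upright_sleep_min
    if sleep_time_min <= 0:
        raise ValueError("position schedule leaves no sleep time")

    def overlaps_upright(s: float, e: float) -> bool:
        i0, i1 = int(s * fs), int(np.ceil(e * fs))
        return bool(upright[i0:i1].any())

    events = _draw_events(cfg, rng, sleep_start, sleep_end, overlaps_upright)

    # --- capacitance channel -------------------------------------------
    # Respiratory rate: bounded random walk around the nominal rate.
    steps = rng.normal(0.0, 0.01, size=n)
    rate = np.clip(cfg.mean_resp_rate + np.cumsum(steps), *cfg.resp_rate_range)
    phase = np.cumsum(2.0 * np.pi * rate / 60.0 * dt)
    # Slow amplitude modulation and baseline drift (random-phase sinusoids).
    ph = rng.uniform(0, 2 * np.pi, size=3)
    amp = cfg.breathing_amplitude * (
        1.0 + 0.15 * np.sin(2 * np.pi * t / 900.0 + ph[0])
    )
    baseline = 0.5 * np.sin(2 * np.pi * t / 1800.0 + ph[1]) \
        + 0.2 * np.sin(2 * np.pi * t / 3600.0 + ph[2])
    suppression = np.ones(n)
    for iv in events:
        factor = (cfg.hypopnea_suppression if iv.type == "hypopnea"
                  else cfg.apnea_suppression)
        suppression[(t >= iv.start) & (t < iv.end)] = factor
    cap = baseline + amp * suppression * np.sin(phase) \
        + rng.normal(0.0, cfg.noise_sd, size=n)

    # --- acceleration channels -----------------------------------------
    grav = np.array([_GRAVITY[c] for c in range(5)])[positions]
    acc = grav + rng.normal(0.0, cfg.acc_noise_sd, size=(n, 3))
    wake = ~in_sleep
    acc[wake] += rng.normal(0.0, cfg.movement_sd, size=(int(wake.sum()), 3))
    # Movement bursts during sleep, kept out of the first/last 10 min of the
    # sleep interval (post-onset consolidation) so truth latency/wake stay
    # well defined under the 10-min quiet-run rule.
    burst_lo, burst_hi = sleep_start + 600.0, sleep_end - 600.0
    if cfg.movement_burst_rate > 0 and burst_hi > burst_lo:
        n_burst = int(rng.poisson(
            cfg.movement_burst_rate * (sleep_end - sleep_start) / 3600.0
        ))
        for _ in range(n_burst):
            b0 = rng.uniform(burst_lo, burst_hi)
            b1 = b0 + rng.uniform(2.0, 10.0)
            sel = (t >= b0) & (t < min(b1, burst_hi))
            acc[sel] += rng.normal(0.0, cfg.movement_sd, size=(int(sel.sum()), 3))

    rec = Recording(
        t=t, cap=cap,
        acc_x=acc[:, 0], acc_y=acc[:, 1], acc_z=acc[:, 2],
        sample_rate=fs, subject_id=f"sim-{cfg.seed}",
    )
    truth = TruthSleep(
        sleep_latency=cfg.sleep_latency,
        morning_wake=cfg.morning_wake,
        upright_time=upright_sleep_min,
        sleep_time=sleep_time_min,
        n_events=len(events),
        ahi=round(60.0 * len(events) / sleep_time_min, 1),
    )
    return SimulatedNight(rec, events, truth, positions)


def simulate_paired_devices(
    cfg: SimConfig, perturb: PerturbationSpec = PerturbationSpec()
) -> tuple[SimulatedNight, EventIntervalSet]:
    """One night plus a jittered copy of its events as a reference scoring.

    The reference device sees the same physiology but scores it imperfectly:
    event onsets and durations are jittered, events are dropped at random,
    and spurious events inserted — enabling device-agreement analyses with a
    known disagreement process.
    """
    night = simulate_night(cfg)
    rng = np.random.default_rng([cfg.seed, 9001])
    t_max = night.recording.duration_seconds
    ref: list[EventInterval] = []
    for iv in night.truth_events:
        if rng.random() < perturb.drop_prob:
            continue
        start = iv.start + rng.normal(0.0, perturb.onset_jitter_sd)
        dur = max(10.0, iv.duration + rng.normal(0.0, perturb.duration_jitter_sd))
        start = min(max(start, 0.0), t_max - dur)
        ref.append(EventInterval(start, start + dur, iv.type))
    if perturb.insert_rate > 0:
        for _ in range(int(rng.poisson(perturb.insert_rate * t_max / 3600.0))):
            dur = rng.uniform(*cfg.event_duration_range)
            start = rng.uniform(0.0, t_max - dur)
            ref.append(EventInterval(start, start + dur, "obstructive"))
    return night, EventIntervalSet(ref)


def simulate_cohort(
    n_nights: int,
    base_config: SimConfig = SimConfig(),
    target_ahis: Sequence[float] | None = None,
    seed: int = 0,
) -> list[SimulatedNight]:
    """A cohort of independent nights with varying severity.

    Target AHIs cycle through ``target_ahis`` (default draws across the
    severity bands: 2, 10, 20, 40 events/h); per-night seeds derive from
    ``seed`` so the cohort is reproducible as a whole.
    """
    if target_ahis is None:
        target_ahis = (2.0, 10.0, 20.0, 40.0)
    nights = []
    for i in range(n_nights):
        cfg = replace(
            base_config,
            target_ahi=float(target_ahis[i % len(target_ahis)]),
            seed=int(np.random.default_rng([seed, i]).integers(2**31 - 1)),
        )
        nights.append(simulate_night(cfg))
    return nights
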