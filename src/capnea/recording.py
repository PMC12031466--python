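"""Recording data model, CSV readers/writers, and event-label synchronization.

A :class:`Recording` is one overnight, uniformly sampled multichannel trace
from the abdomen-worn sensor: a capacitance channel tracking abdominal
breathing movement and a three-axis accelerometer (in g), nominally at 5 Hz.
Apnea annotations are interval lists (:class:`EventIntervalSet`) on the same
clock; :func:`label_samples` and :func:`events_from_labels` convert between
interval and per-sample representations.

On-disk formats are plain CSV: recordings with header ``time,cap,ax,ay,az``
(time in seconds from recording start, acceleration in g) and annotations
with header ``start,end,type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventInterval",
    "EventIntervalSet",
    "EVENT_TYPES",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "label_samples",
    "events_from_labels",
    "shift_events",
]

#: Recognised annotation categories.  The detector itself is binary
#: (apnea vs normal); subtypes are carried through as metadata only.
EVENT_TYPES = ("obstructive", "central", "mixed", "hypopnea", "predicted")

#: Timestamp jitter tolerance, as a fraction of the sample period.  Larger
#: gaps are rejected rather than imputed.
JITTER_TOL = 0.1


class FormatError(ValueError):
    """Raised when an on-disk file does not conform to the expected dialect."""


class RecordingValidationError(ValueError):
    """Raised when channel data violate the Recording invariants."""


@dataclass
class Recording:
    """A synchronized 5 Hz multichannel night.

    Parameters
    ----------
    t : array of float
        Sample times in seconds since recording start, strictly increasing
        and uniform to within ``JITTER_TOL`` of a sample period.
    cap : array of float
        Capacitance (arbitrary units) tracking abdominal movement.
    acc_x, acc_y, acc_z : array of float
        Acceleration per axis, in g.
    sample_rate : float
        Nominal sampling rate in Hz (the device streams at 5 Hz).
    subject_id : str
        Opaque subject identifier.
    """

    t: np.ndarray
    cap: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    sample_rate: float = 5.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("t", "cap", "acc_x", "acc_y", "acc_z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        for name in ("cap", "acc_x", "acc_y", "acc_z"):
            if getattr(self, name).size != n:
                raise RecordingValidationError(
                    f"channel {name!r} has length {getattr(self, name).size}, "
                    f"expected {n}"
                )
        if n == 0:
            raise RecordingValidationError("empty recording")
        if self.sample_rate <= 0:
            raise RecordingValidationError("sample_rate must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise RecordingValidationError(
                    f"timestamps not strictly increasing at index {i + 1} "
                    f"(t={self.t[i + 1]!r})"
                )
            period = 1.0 / self.sample_rate
            if np.any(np.abs(dt - period) > JITTER_TOL * period):
                i = int(np.argmax(np.abs(dt - period) > JITTER_TOL * period))
                raise RecordingValidationError(
                    f"non-uniform sampling at index {i + 1}: gap {dt[i]:.6g} s "
                    f"vs nominal {period:.6g} s (tolerance {JITTER_TOL} period)"
                )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_minutes(self) -> float:
        """Recording duration in minutes (n_samples / rate / 60)."""
        return self.n_samples / self.sample_rate / 60.0

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sample_rate

    def accel(self) -> np.ndarray:
        """(n, 3) array of the acceleration channels."""
        return np.column_stack([self.acc_x, self.acc_y, self.acc_z])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "cap": self.cap,
                "ax": self.acc_x,
                "ay": self.acc_y,
                "az": self.acc_z,
            }
        )


@dataclass(frozen=True)
class EventInterval:
    """One scored breathing-disordered event, ``[start, end)`` in seconds."""

    start: float
    end: float
    type: str = "obstructive"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(
                f"interval end must exceed start (got [{self.start}, {self.end}))"
            )
        if self.type not in EVENT_TYPES:
            raise ValueError(
                f"unknown event type {self.type!r}; expected one of {EVENT_TYPES}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


class EventIntervalSet:
    """An ordered collection of :class:`EventInterval`.

    Intervals are kept sorted by start time.  The set is immutable in
    practice: transforming operations return new sets.
    """

    def __init__(self, intervals: Iterable[EventInterval] = ()) -> None:
        self._intervals: tuple[EventInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.start, iv.end))
        )

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[EventInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> EventInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventIntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"EventIntervalSet(n={len(self)})"

    @property
    def starts(self) -> np.ndarray:
        return np.array([iv.start for iv in self._intervals], dtype=float)

    @property
    def ends(self) -> np.ndarray:
        return np.array([iv.end for iv in self._intervals], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts if len(self) else np.empty(0)

    def total_duration(self) -> float:
        return float(self.durations.sum()) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": self.starts,
                "end": self.ends,
                "type": [iv.type for iv in self._intervals],
            }
        )

    def clip(self, lo: float, hi: float) -> "EventIntervalSet":
        """Intersect every interval with ``[lo, hi)``, dropping empties."""
        out = []
        for iv in self._intervals:
            s, e = max(iv.start, lo), min(iv.end, hi)
            if e > s:
                out.append(EventInterval(s, e, iv.type))
        return EventIntervalSet(out)


# ---------------------------------------------------------------------------
# I/O


_REC_COLUMNS = ("time", "cap", "ax", "ay", "az")


def read_recording(path: str | Path, dialect: str = "csv", *,
                   subject_id: str | None = None) -> Recording:
    """Read a recording from the canonical columnar CSV dialect.

    The file must contain the columns ``time,cap,ax,ay,az``.  Timestamps
    must be strictly increasing and uniform within tolerance; the sample
    rate is inferred from the median time step.
    """
    if dialect != "csv":
        raise FormatError(f"unknown dialect {dialect!r}; only 'csv' is supported")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    t = df["time"].to_numpy(dtype=float)
    if t.size > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = 5.0
    return Recording(
        t=t,
        cap=df["cap"].to_numpy(dtype=float),
        acc_x=df["ax"].to_numpy(dtype=float),
        acc_y=df["ay"].to_numpy(dtype=float),
        acc_z=df["az"].to_numpy(dtype=float),
        sample_rate=rate,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as canonical CSV, round-trip lossless.

    Floats are rendered with repr precision (up to 17 significant digits)
    so that read-back reproduces every channel bit-exactly.
    """
    rec.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> EventIntervalSet:
    """Read an annotation CSV with header ``start,end,type``."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in ("start", "end", "type") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return EventIntervalSet(
        EventInterval(float(r.start), float(r.end), str(r.type))
        for r in df.itertuples(index=False)
    )


def write_events(events: EventIntervalSet, path: str | Path) -> None:
    events.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Label synchronization


def label_samples(rec: Recording, events: EventIntervalSet) -> np.ndarray:
    """Per-sample binary apnea labels from event intervals.

    Sample *i* is labeled 1 iff its timestamp falls within an annotated
    event, using the half-open convention ``start <= t_i < end`` so that
    back-to-back events never double-count a sample.

    Raises
    ------
    ValueError
        If any interval lies outside the recording span.
    """
    t0 = rec.t[0]
    t_end = rec.t[-1] + 1.0 / rec.sample_rate
    for iv in events:
        if iv.start < t0 - 1e-9 or iv.end > t_end + 1e-9:
            raise ValueError(
                f"event [{iv.start}, {iv.end}) outside recording span "
                f"[{t0}, {t_end})"
            )
    labels = np.zeros(rec.n_samples, dtype=np.int8)
    for iv in events:
        labels[(rec.t >= iv.start) & (rec.t < iv.end)] = 1
    return labels


def events_from_labels(labels: Sequence[int] | np.ndarray, sample_rate: float,
                       t0: float = 0.0, type: str = "predicted") -> EventIntervalSet:
    """Maximal runs of 1s in a binary series, as intervals on the sample grid.

    The run covering samples ``i..j`` (inclusive) becomes the interval
    ``[t0 + i/rate, t0 + (j+1)/rate)``, so composing with
    :func:`label_samples` recovers grid-aligned intervals exactly.
    """
    lab = np.asarray(labels)
    if lab.size == 0 or not lab.any():
        return EventIntervalSet()
    if not np.isin(lab, (0, 1)).all():
        raise ValueError("labels must be binary")
    padded = np.concatenate([[0], lab, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive sample index
    # divide (not multiply by the period) so boundaries land bit-exactly on
    # the t = i / rate sample grid
    return EventIntervalSet(
        EventInterval(t0 + s / sample_rate, t0 + e / sample_rate, type)
        for s, e in zip(starts, ends)
    )


def shift_events(events: EventIntervalSet, offset: float) -> EventIntervalSet:
    """Constant-offset clock shift for device synchronization."""
    return EventIntervalSet(
        EventInterval(iv.start + offset, iv.end + offset, iv.type) for iv in events
    )
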