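"""Per-sample feature extraction: the four model channels.

The classifier consumes four channels per sample, all aligned to the
recording clock:

1. ``norm_cap`` — capacitance smoothed with a Savitzky–Golay filter
   (window 11 samples, order 3) then z-normalized within a centered moving
   window, so the breathing oscillation has comparable scale across the
   night and across subjects.
2. ``acc_len`` — Euclidean length of the acceleration vector in g;
   ≈ 1 g when the body is still, excursions during movement.
3. ``gap`` — local max−min of the smoothed capacitance in a five-sample
   (1 s at 5 Hz) moving window, a per-second respiratory-effort amplitude;
   collapses toward 0 during apneas.
4. ``position_code`` — body position from the gravity direction:
   0 upright, 1 supine, 2 prone, 3 left, 4 right.

Position classification uses the tilt angles

    roll  = atan2(a_z, a_y)           (wrapped to [0, 360) degrees)
    pitch = atan2(sqrt(a_y^2 + a_z^2), -a_x)   (degrees)

with a first-match-wins rule cascade: upright when |a_x|/‖a‖ ≈ 1 or
pitch > 109°; otherwise supine / prone / left / right from roll sectors
(supine 247.5–292.5°, prone 67.5–112.5°, left 112.5–247.5°, right the
remaining wrap-around sector), each also reachable directly when the
corresponding axis component ≈ ±1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

from .recording import Recording

__all__ = [
    "FeatureConfig",
    "FeatureFrame",
    "OrientationAngles",
    "POSITION_NAMES",
    "savgol_smooth",
    "normalize_windowed",
    "local_gap",
    "accel_length",
    "orientation_angles",
    "classify_position",
    "build_features",
]

POSITION_NAMES = ("upright", "supine", "prone", "left", "right")
POSITION_UPRIGHT, POSITION_SUPINE, POSITION_PRONE, POSITION_LEFT, POSITION_RIGHT = range(5)

_EPS = 1e-8


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable feature-extraction settings.

    ``norm_window`` is not dictated by the sensor protocol; the default of
    300 samples (60 s at 5 Hz) spans several breath cycles at 15 breaths/min
    while still adapting to baseline drift.
    """

    sg_window: int = 11          # Savitzky–Golay window, samples
    sg_order: int = 3            # Savitzky–Golay polynomial order
    norm_window: int = 300       # z-normalization window, samples
    gap_window: int = 5          # local-gap window, samples (1 s at 5 Hz)
    axis_tol: float = 0.9        # |component|/norm above which an axis is "≈ 1"


@dataclass
class FeatureFrame:
    """The four aligned model channels for one recording."""

    norm_cap: np.ndarray
    acc_len: np.ndarray
    gap: np.ndarray
    position_code: np.ndarray
    sample_rate: float = 5.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        n = self.norm_cap.size
        for name in ("acc_len", "gap", "position_code"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} misaligned: "
                                 f"{getattr(self, name).size} != {n}")
        if not np.isin(self.position_code, range(5)).all():
            raise ValueError("position_code values must lie in 0..4")
        if np.any(self.gap < 0):
            raise ValueError("gap must be non-negative")

    def __len__(self) -> int:
        return self.norm_cap.size

    def to_array(self) -> np.ndarray:
        """(n, 4) float matrix for the models; position scaled to [0, 1]."""
        return np.column_stack(
            [self.norm_cap, self.acc_len, self.gap, self.position_code / 4.0]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "norm_cap": self.norm_cap,
                "acc_len": self.acc_len,
                "gap": self.gap,
                "position_code": self.position_code,
            }
        )


@dataclass(frozen=True)
class OrientationAngles:
    """Tilt angles in degrees; roll wrapped to [0, 360)."""

    roll: float
    pitch: float


def savgol_smooth(cap: np.ndarray, window: int = 11, order: int = 3) -> np.ndarray:
    """Savitzky–Golay least-squares polynomial smoothing.

    Window 11 / order 3 captures one peak and one valley of the breathing
    oscillation at a 5 Hz sampling rate.  Edges use the standard polynomial
    fit of the terminal window; output length equals input length.
    """
    cap = np.asarray(cap, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if cap.size < window:
        raise ValueError(f"series of length {cap.size} shorter than window {window}")
    return savgol_filter(cap, window_length=window, polyorder=order, mode="interp")


def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Start/stop of the centered window at each index; shrinks at edges."""
    idx = np.arange(n)
    half = window // 2
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx - half + window, None, n)
    return lo, hi


def normalize_windowed(cap: np.ndarray, window: int = 300) -> np.ndarray:
    """Moving-window z-normalization of the capacitance signal.

    Each sample is replaced by ``(x - mean) / max(sd, eps)`` where mean and
    population SD are taken over a window centered on the sample (shrunk at
    the recording edges, never padded).  A constant window maps to 0 via the
    epsilon guard.
    """
    x = np.asarray(cap, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    n = x.size
    if n == 0:
        return x.copy()
    lo, hi = _window_bounds(n, window)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cnt = (hi - lo).astype(float)
    mean = (c1[hi] - c1[lo]) / cnt
    var = (c2[hi] - c2[lo]) / cnt - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    return (x - mean) / np.maximum(sd, _EPS)


def local_gap(cap: np.ndarray, window: int = 5) -> np.ndarray:
    """Max − min of the capacitance within a centered moving window.

    At 5 Hz the default 5-sample window measures the per-second amplitude of
    respiratory effort.  Edge windows shrink (nearest-edge filtering yields
    exactly the shrunken-window extrema since padding repeats an in-window
    sample).
    """
    x = np.asarray(cap, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    hi = maximum_filter1d(x, size=window, mode="nearest")
    lo = minimum_filter1d(x, size=window, mode="nearest")
    return hi - lo


def accel_length(ax, ay, az) -> np.ndarray | float:
    """Euclidean length of the acceleration vector, in g."""
    return np.sqrt(np.square(ax) + np.square(ay) + np.square(az))


def orientation_angles(ax: float, ay: float, az: float) -> OrientationAngles:
    """Roll and pitch of a single gravity vector, in degrees.

    Roll (horizontal rotation) is atan2(a_z, a_y) wrapped to [0, 360);
    pitch (forward/backward tilt) is atan2(sqrt(a_y² + a_z²), −a_x).
    """
    if ax == 0.0 and ay == 0.0 and az == 0.0:
        raise ValueError("zero acceleration vector has undefined orientation")
    roll = float(np.degrees(np.arctan2(az, ay))) % 360.0
    pitch = float(np.degrees(np.arctan2(np.hypot(ay, az), -ax)))
    return OrientationAngles(roll=roll, pitch=pitch)


def classify_position(ax, ay, az, axis_tol: float = 0.9):
    """Body-position code(s) from gravity direction; vectorized.

    First-match-wins cascade over upright → supine → prone → left → right.
    "≈ ±1" means the axis component divided by the vector norm is within
    ``1 - axis_tol`` of ±1, i.e. |component|/‖a‖ ≥ axis_tol.  Scale-invariant
    by construction.  Scalar inputs return a scalar code.
    """
    ax_a, ay_a, az_a = np.atleast_1d(np.asarray(ax, dtype=float)), \
        np.atleast_1d(np.asarray(ay, dtype=float)), \
        np.atleast_1d(np.asarray(az, dtype=float))
    norm = np.sqrt(ax_a**2 + ay_a**2 + az_a**2)
    if np.any(norm == 0):
        raise ValueError("zero acceleration vector has no position")
    axn, ayn, azn = ax_a / norm, ay_a / norm, az_a / norm
    roll = np.degrees(np.arctan2(az_a, ay_a)) % 360.0
    pitch = np.degrees(np.arctan2(np.hypot(ay_a, az_a), -ax_a))
    # Roll sectors apply at pitch <= 109 (boundary included so the cascade
    # covers the whole sphere); upright claims pitch > 109.
    tilted = pitch <= 109.0
    upright = (np.abs(axn) >= axis_tol) | (pitch > 109.0)
    supine = (azn <= -axis_tol) | (tilted & (roll >= 247.5) & (roll < 292.5))
    prone = (azn >= axis_tol) | (tilted & (roll >= 67.5) & (roll < 112.5))
    left = (ayn <= -axis_tol) | (tilted & (roll >= 112.5) & (roll < 247.5))
    right = (ayn >= axis_tol) | (tilted & ((roll >= 292.5) | (roll < 67.5)))
    code = np.select(
        [upright, supine, prone, left, right],
        [POSITION_UPRIGHT, POSITION_SUPINE, POSITION_PRONE,
         POSITION_LEFT, POSITION_RIGHT],
        default=-1,
    )
    if np.any(code < 0):  # pragma: no cover - cascade covers the sphere
        raise AssertionError("position cascade left a direction unlabeled")
    if np.isscalar(ax) or np.asarray(ax).ndim == 0:
        return int(code[0])
    return code.astype(np.int8)


def build_features(rec: Recording, config: FeatureConfig | None = None) -> FeatureFrame:
    """Extract the aligned 4-channel FeatureFrame from a recording.

    Capacitance is smoothed, then z-normalized in a moving window; the gap
    channel is computed on the *smoothed* (pre-normalization) capacitance so
    its scale stays decoupled from the normalization; acceleration length
    and body position are per-sample.
    """
    cfg = config or FeatureConfig()
    smoothed = savgol_smooth(rec.cap, cfg.sg_window, cfg.sg_order)
    return FeatureFrame(
        norm_cap=normalize_windowed(smoothed, cfg.norm_window),
        acc_len=np.asarray(accel_length(rec.acc_x, rec.acc_y, rec.acc_z)),
        gap=local_gap(smoothed, cfg.gap_window),
        position_code=classify_position(
            rec.acc_x, rec.acc_y, rec.acc_z, cfg.axis_tol
        ),
        sample_rate=rec.sample_rate,
        subject_id=rec.subject_id,
    )
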