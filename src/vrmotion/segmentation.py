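"""Movement segmentation from the combined-controller speed statistic.

The scalar speed statistic Omega(t) combines the instantaneous speeds of
the two controllers (mean of the two by default) computed by finite
differences of their global positions.  Intervals of movement are maximal
runs where Omega exceeds a speed threshold (default 0.077 m/s) for longer
than a minimum duration (default 0.2 s); consecutive interval pairs —
outward excursion and return — together with the dwell between them form
one repetition segment.  A clean calibration of 5 gestures x 5
repetitions therefore yields 50 intervals and 25 segments.

Both thresholds are empirical and per-participant; the defaults are the
values used for cursor-protocol data at 89 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .session import GESTURES, SessionValidationError

__all__ = [
    "DEFAULT_SPEED_THRESHOLD",
    "DEFAULT_MIN_DURATION",
    "Interval",
    "Segment",
    "omega",
    "detect_intervals",
    "build_segments",
    "segment_session",
]

logger = logging.getLogger(__name__)

DEFAULT_SPEED_THRESHOLD = 0.077  # m/s
DEFAULT_MIN_DURATION = 0.2  # s


@dataclass(frozen=True)
class Interval:
    """Half-open index range [start, end) of sustained movement."""

    start: int
    end: int
    role: str = "outward"  # or "return"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SessionValidationError("interval end must exceed start")
        if self.role not in {"outward", "return"}:
            raise SessionValidationError(f"unknown interval role {self.role!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Segment:
    """One repetition: outward interval + enclosed dwell + return interval."""

    start: int
    end: int
    outward: Interval
    return_: Interval
    label: str
    repetition: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SessionValidationError("segment end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def intervals(self) -> tuple[Interval, Interval]:
        return (self.outward, self.return_)


def omega(
    right_positions: np.ndarray,
    left_positions: np.ndarray,
    dt: float,
    rule: str = "mean",
) -> np.ndarray:
    """Per-step combined speed statistic of the two controllers (m/s).

    ``rule`` selects how the two instantaneous speeds ||dP||/dt combine:
    ``mean`` (default; robust to one-sided jitter), ``max``, or
    ``midpoint`` (speed of the midpoint trajectory).  Output length is
    N - 1 (forward-difference stencil).
    """
    right_positions = np.asarray(right_positions, float)
    left_positions = np.asarray(left_positions, float)
    if right_positions.shape != left_positions.shape:
        raise SessionValidationError("controller position series must be aligned")
    if right_positions.shape[0] < 2:
        raise SessionValidationError("need at least 2 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    v_r = np.linalg.norm(np.diff(right_positions, axis=0), axis=1) / dt
    v_l = np.linalg.norm(np.diff(left_positions, axis=0), axis=1) / dt
    if rule == "mean":
        return 0.5 * (v_r + v_l)
    if rule == "max":
        return np.maximum(v_r, v_l)
    if rule == "midpoint":
        mid = 0.5 * (right_positions + left_positions)
        return np.linalg.norm(np.diff(mid, axis=0), axis=1) / dt
    raise ValueError(f"unknown omega combination rule {rule!r}")


def detect_intervals(
    omega_series: np.ndarray,
    dt: float,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> list[Interval]:
    """Maximal above-threshold runs lasting strictly longer than ``min_duration``.

    A run of k samples spans (k - 1) * dt seconds endpoint to endpoint, so
    the duration criterion keeps runs with at least
    ceil(min_duration / dt) + 1 samples.  Roles alternate
    outward/return starting with outward.
    """
    if speed_threshold <= 0 or min_duration <= 0:
        raise ValueError("thresholds must be positive")
    omega_series = np.asarray(omega_series, float)
    above = omega_series > speed_threshold
    min_samples = int(np.ceil(min_duration / dt)) + 1

    intervals: list[Interval] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    for start, end in edges.reshape(-1, 2):
        if end - start >= min_samples:
            role = "outward" if len(intervals) % 2 == 0 else "return"
            intervals.append(Interval(int(start), int(end), role))
    return intervals


def build_segments(
    intervals: list[Interval],
    protocol: tuple[str, ...] = GESTURES,
    reps_per_gesture: int = 5,
) -> list[Segment]:
    """Pair consecutive intervals into repetition segments and label them.

    Pairs (1st, 2nd), (3rd, 4th), ... each become one segment spanning
    from the start of the outward interval to the end of the return
    interval.  Class labels follow the known protocol order with
    ``reps_per_gesture`` consecutive repetitions per gesture; segments
    beyond the protocol are labelled ``extra``.  A dangling odd interval
    is dropped with a warning.
    """
    if len(intervals) % 2 == 1:
        warnings.warn(
            "odd interval count; dropping the dangling final interval", stacklevel=2
        )
        intervals = intervals[:-1]
    expected = len(protocol) * reps_per_gesture
    if len(intervals) != 2 * expected:
        warnings.warn(
            f"expected {2 * expected} intervals for a clean calibration, got "
            f"{len(intervals)}",
            stacklevel=2,
        )
    segments: list[Segment] = []
    for k in range(len(intervals) // 2):
        out, ret = intervals[2 * k], intervals[2 * k + 1]
        gesture_idx = k // reps_per_gesture
        label = protocol[gesture_idx] if gesture_idx < len(protocol) else "extra"
        segments.append(
            Segment(
                start=out.start,
                end=ret.end,
                outward=out,
                return_=ret,
                label=label,
                repetition=k % reps_per_gesture + 1,
            )
        )
    return segments


def segment_session(
    session,
    rule: str = "mean",
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    min_duration: float = DEFAULT_MIN_DURATION,
    protocol: tuple[str, ...] = GESTURES,
    reps_per_gesture: int = 5,
) -> list[Segment]:
    """Convenience wrapper: omega -> intervals -> segments for a Session."""
    om = omega(session.right.positions, session.left.positions, session.dt, rule)
    intervals = detect_intervals(om, session.dt, speed_threshold, min_duration)
    return build_segments(intervals, protocol, reps_per_gesture)


def segments_to_frame(segments: list[Segment]):
    """Tabulate segments as a DataFrame (start, end, label, repetition)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "label": [s.label for s in segments],
            "repetition": [s.repetition for s in segments],
        }
    )
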