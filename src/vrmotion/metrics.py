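"""Motor-performance metrics per arm and movement.

Four scalar metrics summarize each repetition of a gesture, computed on
the movement portions (outward and return intervals) of a segment:

- range of motion: maximal distance of the controller from the headset
  along an anatomical axis of {H} (or the Euclidean distance);
- mean speed: average instantaneous speed;
- smoothness: mean speed divided by maximal instantaneous speed, in
  (0, 1] — constant-speed motion scores 1 (the reciprocal max/mean is
  also exposed, since some clinical reports quote the inverted ratio);
- path length: sum of distances between consecutive samples.

Anatomical axes map onto {H} as X = mediolateral, Y = vertical,
Z = anteroposterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segment
from .session import SessionValidationError

__all__ = [
    "MotorMetrics",
    "range_of_motion",
    "mean_speed",
    "smoothness",
    "path_length",
    "segment_metrics",
    "summarize",
]

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2, "mediolateral": 0, "vertical": 1, "anteroposterior": 2}


@dataclass(frozen=True)
class MotorMetrics:
    range_of_motion: float
    mean_speed: float
    smoothness: float
    path_length: float
    label: str
    hand: str
    repetition: int = 0

    def __post_init__(self) -> None:
        for name in ("range_of_motion", "mean_speed", "path_length"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")


def range_of_motion(controller_rel_hmd: np.ndarray, plane: str = "all") -> float:
    """Max over time of |displacement| along ``plane`` ('X','Y','Z' or 'all')."""
    series = np.atleast_2d(np.asarray(controller_rel_hmd, float))
    if series.shape[0] == 0:
        raise SessionValidationError("empty position series")
    if plane == "all":
        return float(np.linalg.norm(series, axis=1).max())
    return float(np.abs(series[:, _AXIS_INDEX[plane]]).max())


def _speeds(positions: np.ndarray, dt: float) -> np.ndarray:
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise SessionValidationError("need at least 2 samples for speed")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.linalg.norm(np.diff(positions, axis=0), axis=1) / dt


def mean_speed(positions: np.ndarray, dt: float) -> float:
    """Arithmetic mean of instantaneous speeds ||dP||/dt."""
    return float(_speeds(positions, dt).mean())


def smoothness(positions: np.ndarray, dt: float, invert: bool = False) -> float:
    """Mean over maximal instantaneous speed (or max/mean if ``invert``).

    Undefined for motionless series; returns NaN then.
    """
    speeds = _speeds(positions, dt)
    peak = speeds.max()
    if peak == 0.0:
        return float("nan")
    ratio = speeds.mean() / peak
    return float(1.0 / ratio) if invert else float(ratio)


def path_length(positions: np.ndarray) -> float:
    """Total arc length: sum of consecutive-sample distances."""
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise SessionValidationError("need at least 2 samples for path length")
    return float(np.linalg.norm(np.diff(positions, axis=0), axis=1).sum())


#: Anatomical axis along which each calibration gesture's range of motion
#: is reported.
GESTURE_PLANE = {"right": "X", "left": "X", "up": "Y", "down": "Y", "forward": "Z"}


def segment_metrics(
    rel_positions: np.ndarray,
    segment: Segment,
    dt: float,
    hand: str,
    plane: str | None = None,
) -> MotorMetrics:
    """Metrics for one controller over one segment's movement intervals.

    ``rel_positions`` is the (N, 3) controller-in-{H} position series the
    segment indexes into.  Speed-based metrics are computed over the
    concatenated outward and return intervals (the dwell is excluded:
    the metrics describe motion, not holding still); range of motion uses
    the whole segment.
    """
    rel_positions = np.asarray(rel_positions, float)
    plane = plane or GESTURE_PLANE.get(segment.label, "all")
    whole = rel_positions[segment.start : segment.end]
    moving_speeds = np.concatenate(
        [_speeds(rel_positions[iv.start : iv.end], dt) for iv in segment.intervals]
    )
    moving_paths = sum(
        path_length(rel_positions[iv.start : iv.end]) for iv in segment.intervals
    )
    peak = moving_speeds.max()
    return MotorMetrics(
        range_of_motion=range_of_motion(whole, plane),
        mean_speed=float(moving_speeds.mean()),
        smoothness=float(moving_speeds.mean() / peak) if peak > 0 else float("nan"),
        path_length=float(moving_paths),
        label=segment.label,
        hand=hand,
        repetition=segment.repetition,
    )


def summarize(table: pd.DataFrame, segments: list[Segment]) -> pd.DataFrame:
    """Mean (SD) of each metric across repetitions, per movement x hand.

    ``table`` is the 30-variable kinematic table whose ``X_H_R`` ...
    ``Z_H_L`` columns carry the controller positions in {H}.  A single
    repetition reports SD 0.
    """
    dt = table.attrs.get("dt")
    if dt is None:
        raise SessionValidationError("variable table is missing its dt attribute")
    rows = []
    for hand, dev in (("right", "R"), ("left", "L")):
        rel = table[[f"{axis}_H_{dev}" for axis in "XYZ"]].to_numpy()
        for seg in segments:
            m = segment_metrics(rel, seg, dt, hand)
            rows.append(
                {
                    "label": m.label,
                    "hand": m.hand,
                    "repetition": m.repetition,
                    "range_of_motion": m.range_of_motion,
                    "mean_speed": m.mean_speed,
                    "smoothness": m.smoothness,
                    "path_length": m.path_length,
                }
            )
    per_rep = pd.DataFrame(rows)
    grouped = per_rep.groupby(["label", "hand"], sort=False)[
        ["range_of_motion", "mean_speed", "smoothness", "path_length"]
    ]
    summary = grouped.agg(["mean", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0])
    summary.columns = [
        f"{metric}_{'sd' if stat == '<lambda_0>' else stat}"
        for metric, stat in summary.columns
    ]
    return summary.reset_index()
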