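"""Per-user calibration: average reach excursion and cursor thresholds.

During calibration the user repeats each gesture five times.  For each
axis the average maximal excursion of the controller midpoint relative to
the instantaneous HMD position,

    d_bar = (1/n) * sum_n  max_t | P_h,n(t) - P_H,n(t) |,

defines the user's range of motion; cursor-control thresholds are placed
at a fixed fraction (default 0.25) of d_bar, so users with a limited range
of motion drive the cursor with proportionally smaller movements.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationProfile",
    "CursorCommand",
    "average_excursion",
    "make_profile",
    "cursor_command",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.25

#: Screen direction for exceedance of each signed axis of {H}: +X is the
#: user's left on screen (mirrored cursor), -X right, +Y up, -Y down, +Z
#: forward.  A signed axis absent here triggers nothing.
DEFAULT_DIRECTION_MAP = {
    ("X", +1): "left",
    ("X", -1): "right",
    ("Y", +1): "up",
    ("Y", -1): "down",
    ("Z", +1): "forward",
}

_AXES = ("X", "Y", "Z")


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationProfile:
    """Per-axis average excursion and derived cursor thresholds (meters)."""

    d_bar: np.ndarray
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    disabled_axes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.d_bar = np.asarray(self.d_bar, dtype=float)
        if self.d_bar.shape != (3,):
            raise CalibrationError("d_bar must be a per-axis 3-vector")
        if np.any(self.d_bar < 0):
            raise CalibrationError("d_bar components must be non-negative")
        if not 0 < self.threshold_fraction <= 1:
            raise CalibrationError("threshold_fraction must lie in (0, 1]")

    @property
    def thresholds(self) -> np.ndarray:
        return self.threshold_fraction * self.d_bar

    def to_json(self) -> str:
        return json.dumps(
            {
                "d_bar": self.d_bar.tolist(),
                "threshold_fraction": self.threshold_fraction,
                "thresholds": self.thresholds.tolist(),
                "disabled_axes": list(self.disabled_axes),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationProfile":
        obj = json.loads(text)
        return cls(
            d_bar=np.asarray(obj["d_bar"], float),
            threshold_fraction=float(obj["threshold_fraction"]),
            disabled_axes=tuple(obj.get("disabled_axes", ())),
        )


@dataclass(frozen=True)
class CursorCommand:
    """Active screen directions with per-axis exceedance magnitudes (m)."""

    directions: frozenset[str]
    exceedances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if {"left", "right"} <= self.directions or {"up", "down"} <= self.directions:
            raise CalibrationError("opposing directions cannot be simultaneously active")

    def __bool__(self) -> bool:
        return bool(self.directions)


def average_excursion(
    repetitions: Sequence[slice],
    midpoint_series: np.ndarray,
    hmd_series: np.ndarray,
) -> np.ndarray:
    """Mean-of-per-repetition-maxima excursion along each axis.

    Parameters
    ----------
    repetitions
        Time slices, one per repetition (typically five).
    midpoint_series, hmd_series
        Aligned (N, 3) global-frame positions of the controller midpoint
        and the HMD.
    """
    midpoint_series = np.asarray(midpoint_series, float)
    hmd_series = np.asarray(hmd_series, float)
    if midpoint_series.shape != hmd_series.shape:
        raise CalibrationError("midpoint and HMD series must be aligned")
    if not repetitions:
        raise CalibrationError("at least one repetition slice is required")
    displacement = np.abs(midpoint_series - hmd_series)
    maxima = []
    for sl in repetitions:
        chunk = displacement[sl]
        if chunk.shape[0] == 0:
            raise CalibrationError(f"empty repetition slice {sl}")
        maxima.append(chunk.max(axis=0))
    return np.mean(maxima, axis=0)


def make_profile(
    d_bar: np.ndarray, fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> CalibrationProfile:
    """Build a profile with thresholds at ``fraction * d_bar`` per axis.

    Axes with zero average excursion cannot define a meaningful threshold;
    they are disabled with a warning rather than made hair-triggered.
    """
    if fraction <= 0:
        raise CalibrationError("threshold fraction must be positive")
    d_bar = np.asarray(d_bar, float)
    disabled = tuple(_AXES[i] for i in range(3) if d_bar[i] == 0.0)
    if disabled:
        warnings.warn(
            f"zero excursion on axes {disabled}; cursor control disabled there",
            stacklevel=2,
        )
    return CalibrationProfile(d_bar, fraction, disabled_axes=disabled)


def cursor_command(
    midpoint_rel_hmd: np.ndarray,
    profile: CalibrationProfile,
    direction_map: dict | None = None,
) -> CursorCommand:
    """Cursor directions whose axis displacement exceeds its threshold.

    Multiple axes may be active at once; there is no dwell-time
    requirement on the displacement.
    """
    direction_map = DEFAULT_DIRECTION_MAP if direction_map is None else direction_map
    disp = np.asarray(midpoint_rel_hmd, float)
    if disp.shape != (3,):
        raise CalibrationError("displacement must be a 3-vector")
    thresholds = profile.thresholds
    active: set[str] = set()
    exceedances: dict[str, float] = {}
    for i, axis in enumerate(_AXES):
        if axis in profile.disabled_axes:
            continue
        magnitude = abs(disp[i]) - thresholds[i]
        if magnitude > 0:
            direction = direction_map.get((axis, int(np.sign(disp[i])) or 1))
            if direction is not None:
                active.add(direction)
                exceedances[axis] = float(magnitude)
    return CursorCommand(frozenset(active), exceedances)
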