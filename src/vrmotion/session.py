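"""Tracked-session containers and delimited-text I/O.

A recording session consists of synchronized 6-DoF pose streams for three
devices: the head-mounted display (HMD) and the right and left hand
controllers.  Each sample carries a 3-D position in meters (global frame
{G}) and an orientation as Tait-Bryan angles in radians (gamma about X,
beta about Y, alpha about Z).  Sessions are stored as plain CSV, one row
per time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEVICES",
    "POSE_FIELDS",
    "NO_MOVEMENT",
    "GESTURES",
    "PoseSample",
    "DeviceTrack",
    "Session",
    "read_session",
    "write_session",
]

#: Device keys in canonical order (HMD, right controller, left controller).
DEVICES = ("hmd", "right", "left")

#: Per-device pose columns: position (m) then Tait-Bryan angles (rad).
POSE_FIELDS = ("x", "y", "z", "gamma", "beta", "alpha")

#: Label used for time steps with no prescribed gesture.
NO_MOVEMENT = "no_movement"

#: The five calibration gestures in protocol order: horizontal shoulder
#: abduction to the right, then to the left, shoulder flexion raising both
#: hands, elbow extension lowering both hands, and a forward push.
GESTURES = ("right", "left", "up", "down", "forward")

DEFAULT_SAMPLE_RATE_HZ = 89.0


def steps_to_seconds(n_steps: float, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> float:
    """Duration in seconds of ``n_steps`` samples at the given rate."""
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    return n_steps / sample_rate_hz


class SessionValidationError(ValueError):
    """Raised when a session or track violates its structural contract."""


@dataclass(frozen=True)
class PoseSample:
    """One timestamped 6-DoF pose.

    Attributes
    ----------
    t : float
        Time in seconds.
    position : ndarray, shape (3,)
        X, Y, Z in meters, in the frame named by ``frame``.
    orientation : ndarray, shape (3,)
        Tait-Bryan angles (gamma, beta, alpha) in radians.
    frame : str
        Frame tag; one of ``{"G", "H", "R", "L"}``.
    """

    t: float
    position: np.ndarray
    orientation: np.ndarray
    frame: str = "G"

    def __post_init__(self) -> None:
        if self.frame not in {"G", "H", "R", "L"}:
            raise SessionValidationError(f"unknown frame tag {self.frame!r}")
        pos = np.asarray(self.position, dtype=float)
        ori = np.asarray(self.orientation, dtype=float)
        if pos.shape != (3,) or ori.shape != (3,):
            raise SessionValidationError("position and orientation must be 3-vectors")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(ori))):
            raise SessionValidationError("pose contains non-finite values")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", ori)


@dataclass
class DeviceTrack:
    """Ordered pose stream for one tracked device.

    ``positions`` is an (N, 3) array in meters, ``orientations`` an (N, 3)
    array of Tait-Bryan angles in radians, both indexed by ``t`` (seconds,
    strictly increasing, nominally spaced at ``1 / sample_rate_hz``).
    """

    device: str
    t: np.ndarray
    positions: np.ndarray
    orientations: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise SessionValidationError(f"unknown device {self.device!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = self.t.shape[0]
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise SessionValidationError("track arrays must be (N,) and (N, 3)")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise SessionValidationError("timestamps must be strictly increasing")
        if self.sample_rate_hz <= 0:
            raise SessionValidationError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    def samples(self) -> Iterable[PoseSample]:
        for i in range(len(self)):
            yield PoseSample(
                t=float(self.t[i]),
                position=self.positions[i],
                orientation=self.orientations[i],
            )


@dataclass
class Session:
    """Three aligned device tracks plus optional per-step gesture labels."""

    hmd: DeviceTrack
    right: DeviceTrack
    left: DeviceTrack
    labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.hmd)
        for track in (self.right, self.left):
            if len(track) != n or not np.array_equal(track.t, self.hmd.t):
                raise SessionValidationError("device tracks must share one time base")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != n:
                raise SessionValidationError("labels must match session length")

    def __len__(self) -> int:
        return len(self.hmd)

    @property
    def t(self) -> np.ndarray:
        return self.hmd.t

    @property
    def sample_rate_hz(self) -> float:
        return self.hmd.sample_rate_hz

    @property
    def dt(self) -> float:
        return self.hmd.dt

    def track(self, device: str) -> DeviceTrack:
        if device not in DEVICES:
            raise SessionValidationError(f"unknown device {device!r}")
        return getattr(self, device)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical wide CSV layout."""
        data: dict[str, np.ndarray] = {"t": self.t}
        for device in DEVICES:
            track = self.track(device)
            for j, name in enumerate(POSE_FIELDS[:3]):
                data[f"{device}_{name}"] = track.positions[:, j]
            for j, name in enumerate(POSE_FIELDS[3:]):
                data[f"{device}_{name}"] = track.orientations[:, j]
        if self.labels is not None:
            data["label"] = self.labels
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
        metadata: dict | None = None,
    ) -> "Session":
        missing = [c for c in session_columns() if c not in frame.columns]
        if missing:
            raise SessionValidationError(f"session table missing columns: {missing}")
        t = frame["t"].to_numpy(dtype=float)
        tracks = {}
        for device in DEVICES:
            pos = frame[[f"{device}_{c}" for c in POSE_FIELDS[:3]]].to_numpy(float)
            ori = frame[[f"{device}_{c}" for c in POSE_FIELDS[3:]]].to_numpy(float)
            tracks[device] = DeviceTrack(device, t, pos, ori, sample_rate_hz)
        labels = frame["label"].to_numpy(object) if "label" in frame.columns else None
        return cls(labels=labels, metadata=metadata or {}, **tracks)


def session_columns() -> list[str]:
    """Required column names of the session CSV schema (label optional)."""
    cols = ["t"]
    for device in DEVICES:
        cols += [f"{device}_{c}" for c in POSE_FIELDS]
    return cols


def read_session(
    path, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
) -> Session:
    """Read a session from CSV, validating the schema strictly.

    Unknown extra columns are ignored with a warning; missing required
    columns raise :class:`SessionValidationError` listing the offenders.
    """
    import warnings

    frame = pd.read_csv(path)
    known = set(session_columns()) | {"label"}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring unknown session columns: {extra}", stacklevel=2)
    return Session.from_frame(frame, sample_rate_hz=sample_rate_hz)


def write_session(session: Session, path) -> None:
    session.to_frame().to_csv(path, index=False)
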