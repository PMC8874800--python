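"""Synthetic VR calibration sessions with ground-truth labels.

Emulates the calibration protocol of a standing user wearing an HMD with
a controller in each hand: five bimanual gestures (reach right, reach
left, raise, lower, push forward), each repeated five times with returns
to a baseline pose between excursions.  Point-to-point movements follow
minimum-jerk (quintic) profiles — the standard model for reaching, with
closed-form speed ratios (mean/peak = 8/15) that make speed-derived
metrics exactly checkable.  Each gesture also drives a programmed set of
controller Tait-Bryan angles (forearm-pronation-like rolls), so the
orientation variables carry the coordinated variance the saliency
analysis is expected to recover.

Sensor noise is modelled as a low-pass-filtered (first-order
autoregressive) Gaussian process with configurable stationary SD and
correlation time, mimicking the temporally correlated jitter of optical
tracking; white noise at 89 Hz would produce finite-difference speed
floors far above any realistic movement-detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import DEFAULT_MIN_DURATION, DEFAULT_SPEED_THRESHOLD, detect_intervals, omega
from .session import DEFAULT_SAMPLE_RATE_HZ, GESTURES, NO_MOVEMENT, DeviceTrack, Session

__all__ = [
    "SubjectParams",
    "GroundTruth",
    "DRIVING_ANGLES",
    "minimum_jerk",
    "minimum_jerk_speed",
    "generate_gesture",
    "generate_calibration_session",
    "generate_impaired_session",
]

#: Global-frame direction of each gesture's excursion (unit vectors).
GESTURE_DIRECTIONS = {
    "right": np.array([1.0, 0.0, 0.0]),
    "left": np.array([-1.0, 0.0, 0.0]),
    "up": np.array([0.0, 1.0, 0.0]),
    "down": np.array([0.0, -1.0, 0.0]),
    "forward": np.array([0.0, 0.0, 1.0]),
}

#: Controller-orientation variables driven by each gesture (the programmed
#: ground truth the saliency analysis should recover).  Lateral reaches
#: roll and yaw both forearms; raising flexes everything; lowering mostly
#: rolls; the forward push pronates into yaw.
DRIVING_ANGLES = {
    "right": ("gamma_H_R", "alpha_H_R", "gamma_H_L", "alpha_H_L"),
    "left": ("gamma_H_R", "alpha_H_R", "gamma_H_L", "alpha_H_L"),
    "up": (
        "gamma_H_R", "beta_H_R", "alpha_H_R",
        "gamma_H_L", "beta_H_L", "alpha_H_L",
    ),
    "down": ("gamma_H_R", "alpha_H_R", "gamma_H_L", "alpha_H_L"),
    "forward": ("beta_H_R", "alpha_H_R", "beta_H_L", "alpha_H_L"),
}

_ANGLE_INDEX = {"gamma": 0, "beta": 1, "alpha": 2}


@dataclass(frozen=True)
class SubjectParams:
    """Simulated-subject kinematic and sensor parameters.

    Amplitudes are comfortable adult reach excursions; durations match
    unhurried prescribed movements; noise reflects consumer optical
    tracking (~2 mm, ~0.5 deg stationary jitter with ~1 s correlation).
    """

    reach_amplitudes: dict = field(
        default_factory=lambda: {
            "right": 0.50, "left": 0.50, "up": 0.45, "down": 0.40, "forward": 0.45
        }
    )
    angle_amplitude: float = 0.6  # rad, excursion of each driven angle
    movement_duration: float = 1.0  # s, one out (or return) reach
    hold_duration: float = 0.6  # s, dwell at full extension
    baseline_duration: float = 0.8  # s, dwell at the baseline pose
    position_noise_sd: float = 0.002  # m, slow correlated jitter
    angle_noise_sd: float = np.deg2rad(0.5)  # rad, slow correlated jitter
    noise_corr_time: float = 1.0  # s, correlation time of the slow jitter
    position_white_sd: float = 0.0001  # m, per-sample measurement noise
    angle_white_sd: float = np.deg2rad(0.7)  # rad, per-sample measurement noise
    hmd_position_noise_sd: float = 0.003  # m, slow postural sway
    hmd_angle_noise_sd: float = np.deg2rad(0.3)
    left_amplitude_factor: float = 1.0  # right/left asymmetry (1 = symmetric)
    left_speed_factor: float = 1.0  # stretches the affected arm's reach time
    n_subpeaks: int = 1  # >1 -> segmented (multi-peak) reaches
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    hmd_position: tuple = (0.0, 1.60, 0.0)
    right_base: tuple = (0.18, 1.45, 0.30)
    left_base: tuple = (-0.18, 1.45, 0.30)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz


@dataclass
class GroundTruth:
    """What the generator actually produced, for oracle tests."""

    labels: np.ndarray  # per-step class label
    repetitions: list  # (gesture, repetition, start, end) index spans
    driving_variables: dict  # gesture -> programmed orientation variables
    expected_intervals: list  # noise-free detector output [(start, end), ...]


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement 10 t^3 - 15 t^4 + 6 t^5 on [0, 1]."""
    tau = np.clip(np.asarray(tau, float), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """d/dt of :func:`minimum_jerk`; peak 15/8 at the midpoint, mean 1."""
    tau = np.clip(np.asarray(tau, float), 0.0, 1.0)
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def _segmented_profile(tau: np.ndarray, n_subpeaks: int, duty: float = 0.6) -> np.ndarray:
    """Reach split into min-jerk sub-reaches separated by brief pauses.

    Each sub-reach covers 1/n of the amplitude within the first ``duty``
    fraction of its time slot and then holds, giving a multi-peak speed
    profile whose mean/peak ratio is ``duty`` times the single-reach one.
    """
    if n_subpeaks <= 1:
        return minimum_jerk(tau)
    out = np.zeros_like(tau)
    for k in range(n_subpeaks):
        local = (tau * n_subpeaks - k) / duty
        out += minimum_jerk(local) / n_subpeaks
    return out


def _ar1_noise(rng, shape, sd, corr_time, dt):
    """Stationary first-order autoregressive Gaussian noise (burned in)."""
    if sd == 0.0:
        return np.zeros(shape)
    from scipy.signal import lfilter

    a = np.exp(-dt / corr_time)
    b = sd * np.sqrt(1.0 - a * a)
    burn = int(np.ceil(5.0 * corr_time / dt))
    white = rng.standard_normal((shape[0] + burn,) + tuple(shape[1:]))
    return lfilter([b], [1.0, -a], white, axis=0)[burn:]


def _phase_counts(params: SubjectParams) -> dict[str, int]:
    r = params.sample_rate_hz
    return {
        "move": max(2, round(params.movement_duration * r)),
        "hold": max(1, round(params.hold_duration * r)),
        "baseline": max(1, round(params.baseline_duration * r)),
    }


def _build_clean(gesture_sequence, params: SubjectParams):
    """Noise-free trajectories + labels for an ordered list of repetitions.

    ``gesture_sequence`` is a list of (gesture, repetition) pairs.
    """
    counts = _phase_counts(params)
    right_base = np.asarray(params.right_base, float)
    left_base = np.asarray(params.left_base, float)

    pos_r: list[np.ndarray] = []
    pos_l: list[np.ndarray] = []
    ang_r: list[np.ndarray] = []
    ang_l: list[np.ndarray] = []
    labels: list[str] = []
    repetitions = []

    def dwell(n):
        pos_r.append(np.tile(right_base, (n, 1)))
        pos_l.append(np.tile(left_base, (n, 1)))
        ang_r.append(np.zeros((n, 3)))
        ang_l.append(np.zeros((n, 3)))
        labels.extend([NO_MOVEMENT] * n)

    def profile_block(gesture, frac_r, frac_l, n, label):
        """Append a block where each arm's excursion fraction is given."""
        direction = GESTURE_DIRECTIONS[gesture]
        amp = params.reach_amplitudes[gesture]
        amp_l = amp * params.left_amplitude_factor
        pos_r.append(right_base + amp * np.outer(frac_r, direction))
        pos_l.append(left_base + amp_l * np.outer(frac_l, direction))
        block_r = np.zeros((n, 3))
        block_l = np.zeros((n, 3))
        for var in DRIVING_ANGLES[gesture]:
            angle, _, dev = var.split("_")
            if dev == "R":
                block_r[:, _ANGLE_INDEX[angle]] = params.angle_amplitude * frac_r
            else:
                block_l[:, _ANGLE_INDEX[angle]] = (
                    params.angle_amplitude * params.left_amplitude_factor * frac_l
                )
        ang_r.append(block_r)
        ang_l.append(block_l)
        labels.extend([label] * n)

    dwell(counts["baseline"])
    for gesture, rep in gesture_sequence:
        start = len(labels)
        n_move = counts["move"]
        if params.left_speed_factor != 1.0:
            # a slower affected arm stretches the prescribed reach time
            n_move = max(2, round(n_move * params.left_speed_factor))
        tau = np.arange(1, n_move + 1) / n_move
        out_r = minimum_jerk(tau)  # intact arm: single smooth reach
        out_l = _segmented_profile(tau, params.n_subpeaks)
        ones = np.ones(counts["hold"])
        profile_block(gesture, out_r, out_l, n_move, gesture)
        profile_block(gesture, ones, ones, counts["hold"], NO_MOVEMENT)
        profile_block(
            gesture, minimum_jerk(1.0 - tau), _segmented_profile(1.0 - tau, params.n_subpeaks),
            n_move, gesture,
        )
        dwell(counts["baseline"])
        repetitions.append((gesture, rep, start, len(labels) - counts["baseline"]))

    return (
        np.vstack(pos_r),
        np.vstack(pos_l),
        np.vstack(ang_r),
        np.vstack(ang_l),
        np.asarray(labels, dtype=object),
        repetitions,
    )


def _assemble_session(gesture_sequence, params: SubjectParams, seed: int) -> tuple[Session, GroundTruth]:
    rng = np.random.default_rng(seed)
    pos_r, pos_l, ang_r, ang_l, labels, repetitions = _build_clean(gesture_sequence, params)
    n = len(labels)
    dt = params.dt
    t = np.arange(n) * dt

    # noise-free detector expectation, before jitter is added
    clean_omega = omega(pos_r, pos_l, dt)
    expected = [
        (iv.start, iv.end)
        for iv in detect_intervals(clean_omega, dt, DEFAULT_SPEED_THRESHOLD, DEFAULT_MIN_DURATION)
    ]

    tau_c = params.noise_corr_time

    def jitter(sd_slow, sd_white):
        noise = _ar1_noise(rng, (n, 3), sd_slow, tau_c, dt)
        if sd_white > 0:
            noise = noise + sd_white * rng.standard_normal((n, 3))
        return noise

    pos_r = pos_r + jitter(params.position_noise_sd, params.position_white_sd)
    pos_l = pos_l + jitter(params.position_noise_sd, params.position_white_sd)
    ang_r = ang_r + jitter(params.angle_noise_sd, params.angle_white_sd)
    ang_l = ang_l + jitter(params.angle_noise_sd, params.angle_white_sd)
    hmd_pos = np.asarray(params.hmd_position, float) + _ar1_noise(
        rng, (n, 3), params.hmd_position_noise_sd, tau_c, dt
    )
    hmd_ang = _ar1_noise(rng, (n, 3), params.hmd_angle_noise_sd, tau_c, dt)

    rate = params.sample_rate_hz
    session = Session(
        hmd=DeviceTrack("hmd", t, hmd_pos, hmd_ang, rate),
        right=DeviceTrack("right", t, pos_r, ang_r, rate),
        left=DeviceTrack("left", t, pos_l, ang_l, rate),
        labels=labels,
        metadata={"seed": seed, "generator": "vrmotion.synthetic"},
    )
    truth = GroundTruth(
        labels=labels,
        repetitions=repetitions,
        driving_variables={g: DRIVING_ANGLES[g] for g, _ in dict(gesture_sequence).items()}
        if gesture_sequence
        else {},
        expected_intervals=expected,
    )
    return session, truth


def generate_gesture(
    gesture: str, params: SubjectParams | None = None, seed: int = 0, reps: int = 1
) -> tuple[Session, GroundTruth]:
    """One gesture repeated ``reps`` times, with surrounding dwells."""
    params = params or SubjectParams()
    if gesture not in GESTURE_DIRECTIONS:
        raise ValueError(f"unknown gesture {gesture!r}")
    sequence = [(gesture, r + 1) for r in range(reps)]
    return _assemble_session(sequence, params, seed)


def generate_calibration_session(
    params: SubjectParams | None = None, reps: int = 5, seed: int = 0
) -> tuple[Session, GroundTruth]:
    """Full calibration: the five gestures in protocol order, ``reps`` each.

    With ``reps = 5`` the session contains 50 movement excursions forming
    25 repetition units.  Deterministic for a given seed.
    """
    params = params or SubjectParams()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sequence = [(g, r + 1) for g in GESTURES for r in range(reps)]
    return _assemble_session(sequence, params, seed)


def generate_impaired_session(
    params: SubjectParams | None = None,
    reps: int = 5,
    seed: int = 0,
    amplitude_factor: float = 0.5,
    speed_factor: float = 1.5,
    n_subpeaks: int = 3,
) -> tuple[Session, GroundTruth]:
    """Calibration with one degraded (left) arm, for metric-sensitivity tests.

    The affected arm's excursions are scaled down by ``amplitude_factor``
    and its reaches are segmented into ``n_subpeaks`` sub-movements,
    producing lower range of motion, lower mean speed, reduced smoothness
    and relatively longer paths — the signature expected of hemiparetic
    movement.  No clinical claim is attached.
    """
    params = params or SubjectParams()
    impaired = replace(
        params,
        left_amplitude_factor=amplitude_factor,
        left_speed_factor=speed_factor,
        n_subpeaks=n_subpeaks,
    )
    return generate_calibration_session(impaired, reps=reps, seed=seed)
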