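"""6-DoF pose kinematics: rotations, relative frames, velocities, and the
30-variable analysis table.

All orientation math is delegated to :class:`scipy.spatial.transform.Rotation`.
The default Tait-Bryan convention is intrinsic Z-X-Y (yaw about Z, then pitch
about the new X, then roll about the new Y), matching the Unity/Oculus
runtime that produces consumer VR pose logs; the convention is configurable
and the saliency of individual angle variables depends on it.

Relative poses express each controller in the head-centric frame {H}: with
``R_GH`` the HMD orientation and ``P_GH`` its position in the global frame
{G}, a controller at ``(R_GC, P_GC)`` has

    R_HC = R_GH^T @ R_GC
    P_HC = R_GH^T @ (P_GC - P_GH)

i.e. the inverse homogeneous transform of the HMD applied to the controller
pose.  Velocities are finite differences of the global-frame coordinates
(angles unwrapped first), forward difference by default.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .session import Session, SessionValidationError

__all__ = [
    "DEFAULT_CONVENTION",
    "VARIABLE_NAMES",
    "rotation_from_tait_bryan",
    "tait_bryan_from_rotation",
    "relative_orientation",
    "relative_position",
    "controller_midpoint",
    "finite_difference_series",
    "assemble_variable_table",
]

#: Intrinsic rotation order (scipy upper-case seq) applied to (gamma, beta,
#: alpha) = angles about X, Y, Z respectively.
DEFAULT_CONVENTION = "ZXY"

_ANGLE_AXIS = {"X": 0, "Y": 1, "Z": 2}  # gamma, beta, alpha indices

_ORTHO_TOL = 1e-8


class ConfigurationError(ValueError):
    """Unknown convention or otherwise invalid configuration."""


def _angles_in_convention_order(gamma: float, beta: float, alpha: float, convention: str):
    angles = (gamma, beta, alpha)
    return [angles[_ANGLE_AXIS[axis]] for axis in convention]


def rotation_from_tait_bryan(
    gamma, beta, alpha, convention: str = DEFAULT_CONVENTION
) -> np.ndarray:
    """Rotation matrix from Tait-Bryan angles (radians).

    Parameters
    ----------
    gamma, beta, alpha
        Angles about the X, Y and Z axes respectively.  Scalars or
        broadcastable arrays.
    convention
        Intrinsic axis order as an upper-case scipy ``seq`` string using
        each of X, Y, Z once (e.g. ``"ZXY"``, ``"XYZ"``).

    Returns
    -------
    ndarray, shape (3, 3) or (N, 3, 3)
    """
    _check_convention(convention)
    gamma, beta, alpha = np.broadcast_arrays(
        np.asarray(gamma, float), np.asarray(beta, float), np.asarray(alpha, float)
    )
    if not (np.all(np.isfinite(gamma)) and np.all(np.isfinite(beta)) and np.all(np.isfinite(alpha))):
        raise ValueError("Tait-Bryan angles must be finite")
    stacked = np.stack(
        _angles_in_convention_order(gamma, beta, alpha, convention), axis=-1
    )
    return Rotation.from_euler(convention, stacked).as_matrix()


def tait_bryan_from_rotation(
    matrix: np.ndarray, convention: str = DEFAULT_CONVENTION
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`rotation_from_tait_bryan`; returns (gamma, beta, alpha)."""
    _check_convention(convention)
    _check_orthonormal(matrix)
    euler = Rotation.from_matrix(matrix).as_euler(convention)
    # euler columns follow the convention's axis order; map back to X, Y, Z.
    out = np.empty_like(euler)
    for pos, axis in enumerate(convention):
        out[..., _ANGLE_AXIS[axis]] = euler[..., pos]
    return out[..., 0], out[..., 1], out[..., 2]


def _check_convention(convention: str) -> None:
    if sorted(convention) != ["X", "Y", "Z"]:
        raise ConfigurationError(
            f"convention must use each of X, Y, Z once; got {convention!r}"
        )


def _check_orthonormal(matrix: np.ndarray, tol: float = 1e-6) -> None:
    matrix = np.asarray(matrix, float)
    if matrix.shape[-2:] != (3, 3):
        raise SessionValidationError("rotation matrices must be 3x3")
    eye = np.broadcast_to(np.eye(3), matrix.shape)
    if not np.allclose(matrix @ np.swapaxes(matrix, -1, -2), eye, atol=tol):
        raise SessionValidationError("matrix is not orthonormal within tolerance")
    if not np.allclose(np.linalg.det(matrix), 1.0, atol=tol):
        raise SessionValidationError("matrix determinant is not +1 within tolerance")


def relative_orientation(R_GH: np.ndarray, R_GC: np.ndarray) -> np.ndarray:
    """Controller orientation in the HMD frame: ``R_HC = R_GH^T @ R_GC``.

    The parent-frame inverse is the transpose, both inputs being orthonormal.
    Supports stacked (N, 3, 3) inputs.
    """
    _check_orthonormal(R_GH)
    _check_orthonormal(R_GC)
    return np.swapaxes(np.asarray(R_GH, float), -1, -2) @ np.asarray(R_GC, float)


def relative_position(P_GH: np.ndarray, R_GH: np.ndarray, P_GC: np.ndarray) -> np.ndarray:
    """Controller position expressed in {H}: ``R_GH^T @ (P_GC - P_GH)``."""
    _check_orthonormal(R_GH)
    P_GH = np.asarray(P_GH, float)
    P_GC = np.asarray(P_GC, float)
    diff = P_GC - P_GH
    return np.einsum("...ji,...j->...i", np.asarray(R_GH, float), diff)


def controller_midpoint(P_GR: np.ndarray, P_GL: np.ndarray) -> np.ndarray:
    """Midpoint of the two controllers (componentwise mean), same frame."""
    return 0.5 * (np.asarray(P_GR, float) + np.asarray(P_GL, float))


def finite_difference_series(
    series: np.ndarray, dt: float, scheme: str = "forward"
) -> np.ndarray:
    """Differentiate a sampled series by finite differences.

    ``forward`` (default) returns ``(x[1:] - x[:-1]) / dt`` with length
    N - 1, timestamped at the left node; ``central`` returns
    ``(x[2:] - x[:-2]) / (2 dt)`` with length N - 2.
    """
    series = np.asarray(series, float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if series.shape[0] < 2:
        raise SessionValidationError("need at least 2 samples to differentiate")
    if scheme == "forward":
        return np.diff(series, axis=0) / dt
    if scheme == "central":
        if series.shape[0] < 3:
            raise SessionValidationError("central differences need >= 3 samples")
        return (series[2:] - series[:-2]) / (2.0 * dt)
    raise ConfigurationError(f"unknown finite-difference scheme {scheme!r}")


def _variable_names() -> list[str]:
    names = []
    for axis in "XYZ":
        names.append(f"v{axis}_G_H")
    for angle in ("gamma", "beta", "alpha"):
        names.append(f"v{angle}_G_H")
    for dev in ("R", "L"):
        for axis in "XYZ":
            names.append(f"{axis}_H_{dev}")
        for angle in ("gamma", "beta", "alpha"):
            names.append(f"{angle}_H_{dev}")
        for axis in "XYZ":
            names.append(f"v{axis}_G_{dev}")
        for angle in ("gamma", "beta", "alpha"):
            names.append(f"v{angle}_G_{dev}")
    return names


#: The 30 canonical analysis variables, in fixed order: HMD linear and
#: angular velocity in {G}; then per controller (right, left): position in
#: {H}, orientation in {H}, linear velocity in {G}, angular velocity in {G}.
#: A leading ``v`` marks a velocity column.
VARIABLE_NAMES: tuple[str, ...] = tuple(_variable_names())


def assemble_variable_table(
    session: Session,
    convention: str = DEFAULT_CONVENTION,
    scheme: str = "forward",
):
    """Build the 30-column kinematic variable table for a session.

    Angle series are unwrapped before differencing so angular-velocity
    columns are free of 2*pi wrap spikes.  The velocity stencil costs one
    row: with the default forward scheme the table has N - 1 rows and the
    final session row is dropped (first and last for ``central``).

    Returns
    -------
    pandas.DataFrame
        Columns :data:`VARIABLE_NAMES`, indexed by time step.
    """
    import pandas as pd

    for device in ("hmd", "right", "left"):
        if getattr(session, device, None) is None:
            raise SessionValidationError(f"session is missing the {device} track")
    dt = session.dt
    n = len(session)
    if n < 2:
        raise SessionValidationError("session too short for velocity computation")

    if scheme == "forward":
        keep = slice(0, n - 1)
    elif scheme == "central":
        keep = slice(1, n - 1)
    else:
        raise ConfigurationError(f"unknown finite-difference scheme {scheme!r}")

    hmd = session.hmd
    R_GH = rotation_from_tait_bryan(
        hmd.orientations[:, 0], hmd.orientations[:, 1], hmd.orientations[:, 2], convention
    )

    data: dict[str, np.ndarray] = {}
    hmd_ang = np.unwrap(hmd.orientations, axis=0)
    hmd_vel = finite_difference_series(hmd.positions, dt, scheme)
    hmd_angvel = finite_difference_series(hmd_ang, dt, scheme)
    for j, axis in enumerate("XYZ"):
        data[f"v{axis}_G_H"] = hmd_vel[:, j]
    for j, angle in enumerate(("gamma", "beta", "alpha")):
        data[f"v{angle}_G_H"] = hmd_angvel[:, j]

    for dev, key in (("R", "right"), ("L", "left")):
        track = session.track(key)
        R_GC = rotation_from_tait_bryan(
            track.orientations[:, 0],
            track.orientations[:, 1],
            track.orientations[:, 2],
            convention,
        )
        pos_H = relative_position(hmd.positions, R_GH, track.positions)
        R_HC = relative_orientation(R_GH, R_GC)
        g, b, a = tait_bryan_from_rotation(R_HC, convention)
        ang_G = np.unwrap(track.orientations, axis=0)
        vel = finite_difference_series(track.positions, dt, scheme)
        angvel = finite_difference_series(ang_G, dt, scheme)
        for j, axis in enumerate("XYZ"):
            data[f"{axis}_H_{dev}"] = pos_H[keep, j]
        for name, col in zip(("gamma", "beta", "alpha"), (g, b, a)):
            data[f"{name}_H_{dev}"] = col[keep]
        for j, axis in enumerate("XYZ"):
            data[f"v{axis}_G_{dev}"] = vel[:, j]
        for j, angle in enumerate(("gamma", "beta", "alpha")):
            data[f"v{angle}_G_{dev}"] = angvel[:, j]

    table = pd.DataFrame({name: data[name] for name in VARIABLE_NAMES})
    table.attrs["dt"] = dt
    table.attrs["scheme"] = scheme
    if session.labels is not None:
        table.attrs["labels"] = np.asarray(session.labels)[keep]
    return table
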