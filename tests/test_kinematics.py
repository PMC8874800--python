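import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrmotion import (
    Session,
    assemble_variable_table,
    controller_midpoint,
    finite_difference_series,
    relative_orientation,
    relative_position,
    rotation_from_tait_bryan,
    tait_bryan_from_rotation,
)
from vrmotion.kinematics import VARIABLE_NAMES, ConfigurationError
from vrmotion.session import DeviceTrack, SessionValidationError
from vrmotion.synthetic import generate_calibration_session


def _elemental(axis, angle):
    c, s = np.cos(angle), np.sin(angle)
    if axis == "X":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "Y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _compose(gamma, beta, alpha, convention):
    """Brute-force oracle: multiply elemental rotations in intrinsic order."""
    by_axis = {"X": gamma, "Y": beta, "Z": alpha}
    out = np.eye(3)
    for axis in convention:
        out = out @ _elemental(axis, by_axis[axis])
    return out


class TestRotations:
    def test_zero_angles_give_identity(self):
        assert np.allclose(rotation_from_tait_bryan(0, 0, 0), np.eye(3))

    def test_pure_yaw_maps_x_to_y(self):
        R = rotation_from_tait_bryan(0, 0, np.pi / 2)
        assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    @pytest.mark.parametrize("convention", ["ZXY", "XYZ", "ZYX"])
    def test_matches_elemental_composition_oracle(self, convention, rng):
        for _ in range(20):
            g, b, a = rng.uniform(-np.pi, np.pi, 3)
            assert np.allclose(
                rotation_from_tait_bryan(g, b, a, convention),
                _compose(g, b, a, convention),
                atol=1e-12,
            )

    def test_round_trip_recovers_angles(self):
        angles = (0.3, -0.2, 1.1)
        R = rotation_from_tait_bryan(*angles)
        assert np.allclose(tait_bryan_from_rotation(R), angles, atol=1e-10)

    @settings(deadline=None, max_examples=50)
    @given(
        g=st.floats(-1.4, 1.4),
        b=st.floats(-1.4, 1.4),
        a=st.floats(-1.4, 1.4),
    )
    def test_round_trip_property_away_from_gimbal_lock(self, g, b, a):
        R = rotation_from_tait_bryan(g, b, a)
        assert np.allclose(tait_bryan_from_rotation(R), (g, b, a), atol=1e-9)

    def test_output_is_orthonormal_with_unit_determinant(self, rng):
        angles = rng.uniform(-np.pi, np.pi, (100, 3))
        R = rotation_from_tait_bryan(angles[:, 0], angles[:, 1], angles[:, 2])
        assert np.allclose(R @ np.swapaxes(R, -1, -2), np.eye(3), atol=1e-9)
        assert np.allclose(np.linalg.det(R), 1.0, atol=1e-9)

    def test_unknown_convention_raises(self):
        with pytest.raises(ConfigurationError):
            rotation_from_tait_bryan(0, 0, 0, convention="XXY")


class TestRelativePose:
    def test_identity_parent_returns_child(self, rng):
        R = rotation_from_tait_bryan(*rng.uniform(-1, 1, 3))
        assert np.allclose(relative_orientation(np.eye(3), R), R)

    def test_coincident_frames_give_identity(self, rng):
        R = rotation_from_tait_bryan(*rng.uniform(-1, 1, 3))
        assert np.allclose(relative_orientation(R, R), np.eye(3), atol=1e-12)

    def test_relative_orientation_matches_transpose_product(self, rng):
        Ra = rotation_from_tait_bryan(*rng.uniform(-np.pi, np.pi, 3))
        Rb = rotation_from_tait_bryan(*rng.uniform(-np.pi, np.pi, 3))
        assert np.allclose(relative_orientation(Ra, Rb), Ra.T @ Rb, atol=1e-12)

    def test_non_orthonormal_input_rejected(self):
        with pytest.raises(SessionValidationError):
            relative_orientation(np.eye(3) * 2.0, np.eye(3))

    def test_coincident_positions_give_zero(self, rng):
        R = rotation_from_tait_bryan(*rng.uniform(-1, 1, 3))
        p = rng.normal(size=3)
        assert np.allclose(relative_position(p, R, p), 0.0, atol=1e-12)

    def test_pure_translation(self):
        out = relative_position([1, 0, 0], np.eye(3), [1, 1, 0])
        assert np.allclose(out, [0, 1, 0])

    def test_yawed_head_sees_forward_point_on_rotated_axis(self):
        # head yawed +90 deg about vertical Z; a point 1 m ahead along
        # global X lies along the rotated axis of {H}: oracle via the
        # inverse of the full 4x4 homogeneous matrix.
        R = rotation_from_tait_bryan(0, 0, np.pi / 2)
        p_head = np.array([0.0, 0.0, 0.0])
        p_ctrl = np.array([1.0, 0.0, 0.0])
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = p_head
        expected = (np.linalg.inv(T) @ np.append(p_ctrl, 1.0))[:3]
        assert np.allclose(relative_position(p_head, R, p_ctrl), expected, atol=1e-12)

    def test_forward_transform_round_trip(self, rng):
        """relative_position composed with the forward transform is identity."""
        for _ in range(1000):
            R = rotation_from_tait_bryan(*rng.uniform(-np.pi, np.pi, 3))
            p_h, p_c = rng.normal(size=3), rng.normal(size=3)
            rel = relative_position(p_h, R, p_c)
            recovered = R @ rel + p_h
            assert np.linalg.norm(recovered - p_c) < 1e-9


class TestMidpointAndDerivatives:
    def test_midpoint_examples(self, rng):
        assert np.allclose(controller_midpoint([0, 0, 0], [0, 0, 0]), 0.0)
        assert np.allclose(controller_midpoint([1, 2, 3], [3, 2, 1]), [2, 2, 2])
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert np.allclose(controller_midpoint(a, b), (a + b) / 2)

    def test_constant_series_has_zero_velocity(self):
        v = finite_difference_series(np.full(50, 3.7), dt=1 / 89)
        assert v.shape == (49,)
        assert np.allclose(v, 0.0)

    def test_linear_ramp_is_exact(self):
        t = np.arange(100) / 89
        v = finite_difference_series(2.0 * t, dt=1 / 89)
        assert np.allclose(v, 2.0)

    @pytest.mark.parametrize("scheme,order", [("forward", 1), ("central", 2)])
    def test_sinusoid_matches_analytic_derivative(self, scheme, order):
        dt = 1 / 89
        t = np.arange(500) * dt
        v = finite_difference_series(np.sin(t), dt, scheme)
        truth = np.cos(t[:-1]) if scheme == "forward" else np.cos(t[1:-1])
        assert np.abs(v - truth).max() < 2 * dt**order

    def test_too_short_series_rejected(self):
        with pytest.raises(SessionValidationError):
            finite_difference_series(np.array([1.0]), dt=0.01)


def _static_session(n=40):
    t = np.arange(n) / 89
    mk = lambda dev, pos: DeviceTrack(
        dev, t, np.tile(pos, (n, 1)), np.tile([0.1, -0.2, 0.3], (n, 1))
    )
    return Session(
        hmd=mk("hmd", [0.0, 1.6, 0.0]),
        right=mk("right", [0.2, 1.4, 0.3]),
        left=mk("left", [-0.2, 1.4, 0.3]),
    )


class TestVariableTable:
    def test_exactly_30_uniquely_named_columns(self, calibration):
        _, _, table, _ = calibration
        assert table.shape[1] == 30
        assert list(table.columns) == list(VARIABLE_NAMES)
        assert len(set(table.columns)) == 30

    def test_row_count_loses_one_to_the_stencil(self, calibration):
        session, _, table, _ = calibration
        assert len(table) == len(session) - 1
        assert len(table.attrs["labels"]) == len(table)

    def test_static_session_zero_velocities_constant_relative_pose(self):
        table = assemble_variable_table(_static_session())
        velocity_cols = [c for c in table.columns if c.startswith("v")]
        assert np.allclose(table[velocity_cols].to_numpy(), 0.0, atol=1e-12)
        pose_cols = [c for c in table.columns if not c.startswith("v")]
        assert np.allclose(table[pose_cols].std().to_numpy(), 0.0, atol=1e-12)

    def test_clean_session_matches_closed_forms(self, noise_free_params):
        session, truth = generate_calibration_session(noise_free_params, reps=1, seed=0)
        table = assemble_variable_table(session)
        # HMD is exactly static: its velocity columns vanish
        for c in ("vX_G_H", "vgamma_G_H"):
            assert np.allclose(table[c], 0.0, atol=1e-12)
        # relative X of the right controller = base offset +- programmed
        # reach (the rightward then leftward gestures)
        x = table["X_H_R"].to_numpy()
        assert np.isclose(x.min(), 0.18 - 0.50, atol=1e-9)
        assert np.isclose(x.max(), 0.18 + 0.50, atol=1e-9)
        # global linear velocity matches the finite difference of the track
        v = np.diff(session.right.positions[:, 0]) / session.dt
        assert np.allclose(table["vX_G_R"], v, atol=1e-9)
        # driven relative angle reaches its programmed amplitude
        g = table["gamma_H_R"].to_numpy()
        assert np.isclose(g.max(), 0.6, atol=1e-9)

    def test_rigid_global_frame_change_invariance(self, noise_free_params):
        """{H}-frame columns are invariant; global velocities rotate."""
        from vrmotion.kinematics import (
            rotation_from_tait_bryan,
            tait_bryan_from_rotation,
        )

        session, _ = generate_calibration_session(noise_free_params, reps=1, seed=0)
        base = assemble_variable_table(session)

        Q = rotation_from_tait_bryan(0.4, -0.3, 0.8)
        shift = np.array([1.0, -2.0, 0.5])
        tracks = {}
        for dev in ("hmd", "right", "left"):
            tr = session.track(dev)
            R_old = rotation_from_tait_bryan(
                tr.orientations[:, 0], tr.orientations[:, 1], tr.orientations[:, 2]
            )
            g, b, a = tait_bryan_from_rotation(Q @ R_old)
            tracks[dev] = DeviceTrack(
                dev, tr.t, tr.positions @ Q.T + shift, np.stack([g, b, a], axis=1)
            )
        moved = assemble_variable_table(Session(**tracks))

        rel_cols = [c for c in base.columns if c.endswith(("_H_R", "_H_L")) and not c.startswith("v")]
        assert np.allclose(moved[rel_cols], base[rel_cols], atol=1e-8)
        for dev in ("R", "L"):
            v_old = base[[f"v{ax}_G_{dev}" for ax in "XYZ"]].to_numpy()
            v_new = moved[[f"v{ax}_G_{dev}" for ax in "XYZ"]].to_numpy()
            assert np.allclose(v_new, v_old @ Q.T, atol=1e-8)

    def test_angle_unwrapping_prevents_velocity_spikes(self):
        n = 300
        t = np.arange(n) / 89
        angle = np.linspace(0, 6 * np.pi, n)  # three full turns
        wrapped = np.mod(angle + np.pi, 2 * np.pi) - np.pi
        mk = lambda dev, ori: DeviceTrack(
            dev, t, np.tile([0.0, 1.5, 0.2], (n, 1)), ori
        )
        zeros = np.zeros((n, 3))
        ori = np.stack([wrapped, np.zeros(n), np.zeros(n)], axis=1)
        session = Session(hmd=mk("hmd", zeros), right=mk("right", ori), left=mk("left", zeros))
        table = assemble_variable_table(session)
        dt = 1 / 89
        assert np.abs(table["vgamma_G_R"]).max() < np.pi / dt

    def test_missing_device_rejected(self):
        session = _static_session()
        session.left = None
        with pytest.raises(SessionValidationError):
            assemble_variable_table(session)
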