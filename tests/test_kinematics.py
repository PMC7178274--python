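import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rsataper._exceptions import ConsistencyError, DegenerateGeometryError, \
    InputError
from rsataper.kinematics import (
    RigidTransform,
    condition_number,
    correct_reference_point,
    euler_angles,
    fit_rigid_body,
    migration_of_point,
    rotation_from_euler,
)

angles = st.floats(-80.0, 80.0)


def random_markers(rng, n=5, scale=50.0):
    return rng.uniform(-scale, scale, size=(n, 3))


class TestFitRigidBody:
    def test_identity(self, rng):
        pts = random_markers(rng)
        T, rbe = fit_rigid_body(pts, pts)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0.0, atol=1e-12)
        assert rbe < 1e-12

    def test_forward_transform_oracle(self, rng):
        pts = random_markers(rng)
        R = rotation_from_euler(0.0, 0.0, 5.0)
        t = np.array([1.0, 2.0, 3.0])
        T, rbe = fit_rigid_body(pts, pts @ R.T + t)
        assert np.abs(T.rotation - R).max() < 1e-9
        assert np.abs(T.translation - t).max() < 1e-9
        assert rbe < 1e-9

    def test_noise_rbe_below_gate(self, rng):
        pts = np.array([[10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]])
        for _ in range(50):
            moved = pts + rng.normal(0, 0.01, pts.shape)
            _, rbe = fit_rigid_body(pts, moved)
            assert rbe <= 0.35
            assert rbe < 0.1  # order sigma, far below the clinical gate

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            fit_rigid_body(line, line)

    def test_count_mismatch(self, rng):
        pts = random_markers(rng)
        with pytest.raises(InputError):
            fit_rigid_body(pts, pts[:-1])

    def test_reflection_corrected(self, rng):
        pts = random_markers(rng, n=4)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        T, _ = fit_rigid_body(pts, mirrored)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_equivariance(self, rng):
        """Pre-rotating both clouds by Q conjugates the fitted transform."""
        pts = random_markers(rng)
        T0 = RigidTransform.from_euler_translation(2.0, -3.0, 4.0, [0.5, 1.0, -2.0])
        Q = rotation_from_euler(11.0, 23.0, -7.0)
        T, _ = fit_rigid_body(pts @ Q.T, T0.apply(pts) @ Q.T)
        assert np.abs(T.rotation - Q @ T0.rotation @ Q.T).max() < 1e-9
        assert np.abs(T.translation - Q @ T0.translation).max() < 1e-9

    def test_zero_rbe_iff_congruent(self, rng):
        pts = random_markers(rng)
        T0 = RigidTransform.from_euler_translation(1.0, 2.0, 3.0, [1.0, 0.0, 0.0])
        _, rbe = fit_rigid_body(pts, T0.apply(pts))
        assert rbe < 1e-9
        stretched = T0.apply(pts) * np.array([1.01, 1.0, 1.0])
        _, rbe2 = fit_rigid_body(pts, stretched)
        assert rbe2 > 1e-4


class TestConditionNumber:
    def test_collinear_is_infinite(self):
        line = np.array([[0.0, 0, 0], [5, 0, 0], [9, 0, 0], [20, 0, 0]])
        assert condition_number(line) == np.inf

    def test_equilateral_triangle_oracle(self):
        # side 10 mm: brute-force SVD of the centered configuration
        side = 10.0
        tri = side * np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                               [0.5, np.sqrt(3) / 2, 0.0]])
        s_oracle = np.linalg.svd(tri - tri.mean(axis=0), compute_uv=False)
        assert s_oracle[1] == pytest.approx(np.sqrt(50.0), abs=1e-9)
        assert condition_number(tri) == pytest.approx(100.0 / np.sqrt(50.0),
                                                      abs=1e-9)
        assert condition_number(tri) == pytest.approx(14.1421356, abs=1e-6)

    def test_scaling_halves_cn(self, rng):
        pts = random_markers(rng)
        assert condition_number(2.0 * pts) == pytest.approx(
            condition_number(pts) / 2.0, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InputError):
            condition_number([[0.0, 0, 0], [1, 1, 1]])


class TestEulerAngles:
    def test_identity(self):
        ang = euler_angles(RigidTransform.identity())
        assert tuple(ang) == (0.0, 0.0, 0.0)
        assert not ang.gimbal_adjacent

    def test_single_axis(self):
        T = RigidTransform.from_euler_translation(0.0, 5.0, 0.0)
        assert tuple(euler_angles(T)) == pytest.approx((0.0, 5.0, 0.0), abs=1e-12)

    def test_compose_decompose_oracle(self):
        T = RigidTransform.from_euler_translation(2.0, -3.0, 4.0)
        # independent oracle: scipy extrinsic x-y-z composition
        R_oracle = Rotation.from_euler("xyz", [2.0, -3.0, 4.0],
                                       degrees=True).as_matrix()
        assert np.abs(T.rotation - R_oracle).max() < 1e-12
        assert tuple(euler_angles(T)) == pytest.approx((2.0, -3.0, 4.0),
                                                       abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(rx=angles, ry=angles, rz=angles)
    def test_round_trip_property(self, rx, ry, rz):
        T = RigidTransform.from_euler_translation(rx, ry, rz)
        assert tuple(euler_angles(T)) == pytest.approx((rx, ry, rz), abs=1e-8)

    def test_gimbal_flagged(self):
        with pytest.warns(RuntimeWarning):
            ang = euler_angles(RigidTransform.from_euler_translation(0.0, 89.5, 0.0))
        assert ang.gimbal_adjacent


class TestMigrationOfPoint:
    def test_pure_translation_point_independent(self, rng):
        T = RigidTransform(rotation=np.eye(3), translation=[0.5, 0.0, 0.0])
        for p in random_markers(rng, n=5):
            assert migration_of_point(T, p) == pytest.approx([0.5, 0.0, 0.0])

    def test_rotation_oracle(self):
        T = RigidTransform.from_euler_translation(0.0, 0.0, 2.0)
        d = migration_of_point(T, [50.0, 0.0, 0.0])
        expected = [50 * np.cos(np.radians(2)) - 50, 50 * np.sin(np.radians(2)), 0]
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx([-0.0305, 1.745, 0.0], abs=5e-4)

    @settings(max_examples=50, deadline=None)
    @given(rx=angles, ry=angles, rz=angles,
           coords=st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_difference_identity(self, rx, ry, rz, coords):
        """d(p2) - d(p1) = (R - I)(p2 - p1)."""
        T = RigidTransform.from_euler_translation(rx, ry, rz, [1.0, -2.0, 0.5])
        p1, p2 = np.array(coords[:3]), np.array(coords[3:])
        lhs = migration_of_point(T, p2) - migration_of_point(T, p1)
        rhs = (T.rotation - np.eye(3)) @ (p2 - p1)
        assert np.abs(lhs - rhs).max() < 1e-9


class TestReferencePointCorrection:
    def test_no_rotation_no_change(self):
        T = RigidTransform(rotation=np.eye(3), translation=[0.1, 0.2, 0.3])
        d = correct_reference_point(T, [0.1, 0.2, 0.3], [0.0, 0, 0], [50.0, 10, -4])
        assert d == pytest.approx([0.1, 0.2, 0.3], abs=1e-12)

    def test_rotation_oracle(self):
        T = RigidTransform.from_euler_translation(0.0, 0.0, 2.0)
        old = np.zeros(3)
        new = np.array([50.0, 0.0, 0.0])
        d = correct_reference_point(T, migration_of_point(T, old), old, new)
        assert d == pytest.approx(migration_of_point(T, new), abs=1e-12)
        assert d == pytest.approx([-0.0305, 1.745, 0.0], abs=5e-4)

    def test_inconsistent_inputs_rejected(self):
        T = RigidTransform.from_euler_translation(0.0, 0.0, 2.0)
        with pytest.raises(ConsistencyError):
            correct_reference_point(T, [9.9, 9.9, 9.9], [0.0, 0, 0], [1.0, 0, 0])

    def test_chain_additivity(self, rng):
        """Correction is path-independent along chains of reference points."""
        T = RigidTransform.from_euler_translation(3.0, -1.0, 2.0, [0.2, 0.1, 0.0])
        a, b, c = random_markers(rng, n=3)
        d_a = migration_of_point(T, a)
        via_b = correct_reference_point(
            T, correct_reference_point(T, d_a, a, b), b, c)
        direct = correct_reference_point(T, d_a, a, c)
        assert np.abs(via_b - direct).max() < 1e-9


class TestRigidTransform:
    def test_invalid_rotation_rejected(self):
        with pytest.raises(InputError):
            RigidTransform(rotation=np.eye(3) * 1.01, translation=np.zeros(3))

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InputError):
            RigidTransform(rotation=R, translation=np.zeros(3))

    def test_inverse_and_compose(self, rng):
        T = RigidTransform.from_euler_translation(10.0, 20.0, -5.0, [1.0, 2, 3])
        p = rng.uniform(-50, 50, 3)
        assert np.abs(T.inverse().apply(T.apply(p)) - p).max() < 1e-9
        U = RigidTransform.from_euler_translation(-3.0, 7.0, 1.0, [0.0, -1, 4])
        assert np.abs(T.then(U).apply(p) - U.apply(T.apply(p))).max() < 1e-9
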