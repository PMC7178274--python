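import numpy as np
import pytest

from rsataper._exceptions import (
    DegenerateGeometryError,
    InputError,
    InsufficientDataError,
)
from rsataper.egs import (
    ConeModel,
    TaperFrame,
    build_taper_frame,
    construct_virtual_markers,
    fit_cone_axis,
    fit_sphere_center,
    vector_from_frame,
    vector_in_frame,
)
from rsataper.geometry import project_points
from rsataper.kinematics import rotation_from_euler
from rsataper.phantom import cone_silhouette_segments, sphere_silhouette_points

RADIUS = 14.0  # 28 mm ball head
TAPER_HALF_ANGLE = 2.8055  # deg; taper angle 5.611 deg


def sphere_contours(scene, center, n=64):
    return [project_points(scene, i + 1,
                           sphere_silhouette_points(scene.foci[i], center,
                                                    RADIUS, n))
            for i in range(2)]


def cone_silhouettes(scene, cone, s_range=(30.0, 48.0)):
    out = []
    for i in range(2):
        seg3d = cone_silhouette_segments(scene.foci[i], cone, s_range)
        out.append(project_points(scene, i + 1,
                                  seg3d.reshape(-1, 3)).reshape(2, 2, 2))
    return out


class TestSphereFit:
    CENTER = np.array([20.0, -15.0, 180.0])

    def test_two_view_noiseless(self, scene, cal_pair):
        contours = sphere_contours(scene, self.CENTER)
        center, rms = fit_sphere_center(cal_pair, contours, RADIUS)
        assert np.abs(center - self.CENTER).max() < 1e-3
        assert rms < 1e-9

    def test_single_view_noiseless(self, scene, cal_pair):
        contours = sphere_contours(scene, self.CENTER)
        center, _ = fit_sphere_center(cal_pair[:1], contours[:1], RADIUS)
        assert np.abs(center - self.CENTER).max() < 1e-2

    def test_noise_monte_carlo(self, scene, cal_pair, rng):
        contours = sphere_contours(scene, self.CENTER)
        errs = []
        for _ in range(100):
            noisy = [c + rng.normal(0, 0.05, c.shape) for c in contours]
            center, _ = fit_sphere_center(cal_pair, noisy, RADIUS)
            errs.append(np.linalg.norm(center - self.CENTER))
        assert np.median(errs) < 0.1

    def test_partial_arc(self, scene, cal_pair):
        # >= 60 degrees of silhouette arc still recovers the center
        contours = [project_points(scene, i + 1,
                                   sphere_silhouette_points(
                                       scene.foci[i], self.CENTER, RADIUS, 16,
                                       arc=(10.0, 100.0)))
                    for i in range(2)]
        center, _ = fit_sphere_center(cal_pair, contours, RADIUS)
        assert np.abs(center - self.CENTER).max() < 1e-3

    def test_insufficient_contour(self, scene, cal_pair):
        contours = [c[:5] for c in sphere_contours(scene, self.CENTER)]
        with pytest.raises(InsufficientDataError):
            fit_sphere_center(cal_pair, contours, RADIUS)

    def test_bad_radius(self, cal_pair, scene):
        contours = sphere_contours(scene, self.CENTER)
        with pytest.raises(InputError):
            fit_sphere_center(cal_pair, contours, -1.0)


class TestConeFit:
    CONE = ConeModel(axis_point=[30.0, 40.0, 160.0],
                     axis_direction=[0.3, -0.9, 0.2],
                     half_angle=TAPER_HALF_ANGLE)

    @staticmethod
    def direction_error_deg(fit, truth):
        c = abs(float(np.clip(fit.axis_direction @ truth.axis_direction, -1, 1)))
        return np.degrees(np.arccos(c))

    def test_noiseless_recovery(self, scene, cal_pair):
        fit = fit_cone_axis(cal_pair, cone_silhouettes(scene, self.CONE))
        assert self.direction_error_deg(fit, self.CONE) < 0.01
        assert fit.half_angle == pytest.approx(TAPER_HALF_ANGLE, abs=0.005)
        assert np.abs(fit.axis_point - self.CONE.axis_point).max() < 1e-6

    def test_axis_aligned_case(self, scene, cal_pair):
        cone = ConeModel(axis_point=[0.0, 30.0, 150.0],
                         axis_direction=[0.0, -1.0, 0.0],
                         half_angle=TAPER_HALF_ANGLE)
        fit = fit_cone_axis(cal_pair, cone_silhouettes(scene, cone))
        axis = fit.axis_direction * np.sign(fit.axis_direction[1])
        assert np.abs(axis - [0.0, 1.0, 0.0]).max() < 1e-6

    def test_noise_monte_carlo(self, scene, cal_pair, rng):
        sil = cone_silhouettes(scene, self.CONE)
        errs = []
        for _ in range(100):
            noisy = [s + rng.normal(0, 0.05, s.shape) for s in sil]
            fit = fit_cone_axis(cal_pair, noisy)
            errs.append(self.direction_error_deg(fit, self.CONE))
        assert np.median(errs) < 0.5

    def test_cylindrical_flag(self, scene, cal_pair):
        cyl = ConeModel(axis_point=[0.0, 30.0, 150.0],
                        axis_direction=[0.1, -0.99, 0.0],
                        half_angle=0.01)
        fit = fit_cone_axis(cal_pair, cone_silhouettes(scene, cyl))
        assert fit.is_cylindrical

    def test_degenerate_segments_rejected(self, cal_pair):
        # both endpoints on one ray span no plane
        seg = np.array([[[10.0, 10.0], [10.0, 10.0]],
                        [[20.0, 10.0], [25.0, 12.0]]])
        with pytest.raises(DegenerateGeometryError):
            fit_cone_axis(cal_pair, [seg, seg])


class TestVirtualMarkers:
    def test_head_on_axis_degenerates(self):
        vm = construct_virtual_markers([0.0, 100.0, 0.0], [0.0, 0, 0],
                                       [0.0, 1.0, 0.0], [0.0, -30.0, 0.0])
        assert np.allclose(vm.P3, vm.P1)
        assert vm.collinear

    def test_projection_arithmetic_oracle(self):
        vm = construct_virtual_markers([10.0, 100.0, 0.0], [0.0, 0, 0],
                                       [0.0, 1.0, 0.0], [0.0, -30.0, 0.0])
        assert vm.P3 == pytest.approx([0.0, 100.0, 0.0], abs=1e-12)
        assert vm.reference_point == pytest.approx([10 / 3, 170 / 3, 0.0],
                                                   abs=1e-12)
        assert not vm.collinear

    def test_perpendicularity_property(self, rng):
        for _ in range(25):
            p1 = rng.uniform(-50, 50, 3)
            q = rng.uniform(-50, 50, 3)
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            vm = construct_virtual_markers(p1, q, a, rng.uniform(-50, 50, 3))
            assert abs((vm.P1 - vm.P3) @ a) < 1e-9
            # P3 on the axis line
            assert np.linalg.norm(np.cross(vm.P3 - q, a)) < 1e-9

    def test_zero_axis_rejected(self):
        with pytest.raises(InputError):
            construct_virtual_markers([1.0, 2, 3], [0.0, 0, 0],
                                      [0.0, 0.0, 0.0], [5.0, 5, 5])

    def test_reference_moves_with_head_only(self, rng):
        """Moving P1 with the axis and P2 fixed moves the reference point."""
        q, a, tip = [0.0, 0, 0], [0.0, 1.0, 0.0], [0.0, -30.0, 0.0]
        vm1 = construct_virtual_markers([10.0, 100.0, 0.0], q, a, tip)
        vm2 = construct_virtual_markers([10.0, 100.25, 0.0], q, a, tip)
        assert np.linalg.norm(vm2.reference_point - vm1.reference_point) > 0.1


MARKERS = np.array([[18.0, -25.0, 12.0], [-20.0, -55.0, -10.0],
                    [6.0, -95.0, 2.0]])


class TestTaperFrame:
    def test_axis_aligned(self):
        cone = ConeModel(axis_point=[0.0, 0, 0], axis_direction=[0.0, 1.0, 0.0],
                         half_angle=2.8)
        markers = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.0, 10.0, 0]])
        frame = build_taper_frame(cone, markers, side="right")
        assert frame.Y == pytest.approx([0.0, 1.0, 0.0], abs=1e-12)
        assert abs(frame.X[0]) == pytest.approx(1.0, abs=1e-12)
        assert abs(frame.Z[2]) == pytest.approx(1.0, abs=1e-12)

    def test_orthonormal_right_handed(self, rng):
        for _ in range(25):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cone = ConeModel(axis_point=rng.uniform(-50, 50, 3),
                             axis_direction=d, half_angle=2.8)
            markers = MARKERS + rng.normal(0, 5, MARKERS.shape)
            try:
                frame = build_taper_frame(cone, markers)
            except DegenerateGeometryError:
                continue
            M = frame.matrix
            assert np.abs(M.T @ M - np.eye(3)).max() < 1e-12
            assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-12)

    def test_y_parallel_to_cone_axis(self):
        cone = ConeModel(axis_point=[0.0, 0, 0],
                         axis_direction=[0.3, -0.8, 0.1], half_angle=2.8)
        frame = build_taper_frame(cone, MARKERS)
        assert np.linalg.norm(np.cross(frame.Y, cone.axis_direction)) < 1e-9
        assert frame.Y[1] > 0  # signed cranially

    def test_x_in_marker_plane(self):
        cone = ConeModel(axis_point=[0.0, 0, 0],
                         axis_direction=[0.2, 0.9, -0.1], half_angle=2.8)
        frame = build_taper_frame(cone, MARKERS)
        centered = MARKERS - MARKERS.mean(axis=0)
        normal = np.cross(centered[1] - centered[0], centered[2] - centered[0])
        normal /= np.linalg.norm(normal)
        assert abs(frame.X @ normal) < 1e-9

    def test_equivariance_under_small_rotation(self):
        cone = ConeModel(axis_point=[5.0, 10.0, 0.0],
                         axis_direction=[0.3, 0.9, 0.1], half_angle=2.8)
        frame = build_taper_frame(cone, MARKERS)
        Q = rotation_from_euler(4.0, -3.0, 5.0)
        cone_rot = ConeModel(axis_point=Q @ cone.axis_point,
                             axis_direction=Q @ cone.axis_direction,
                             half_angle=2.8)
        frame_rot = build_taper_frame(cone_rot, MARKERS @ Q.T)
        assert np.abs(frame_rot.matrix - Q @ frame.matrix).max() < 1e-9

    def test_degenerate_axis_rejected(self):
        markers = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.0, 10.0, 0]])
        cone = ConeModel(axis_point=[0.0, 0, 0], axis_direction=[0.0, 0, 1.0],
                         half_angle=2.8)
        with pytest.raises(DegenerateGeometryError):
            build_taper_frame(cone, markers)


class TestVectorInFrame:
    def frame(self):
        cone = ConeModel(axis_point=[0.0, 0, 0],
                         axis_direction=[0.3, 0.9, 0.2], half_angle=2.8)
        return build_taper_frame(cone, MARKERS)

    def test_axis_vector(self):
        frame = self.frame()
        assert vector_in_frame(frame, 3.0 * frame.Y) == pytest.approx(
            [0.0, 3.0, 0.0], abs=1e-12)

    def test_isometry(self, rng):
        frame = self.frame()
        for _ in range(20):
            v = rng.normal(size=3) * 10
            comp = vector_in_frame(frame, v)
            assert np.linalg.norm(comp) == pytest.approx(np.linalg.norm(v),
                                                         abs=1e-12)

    def test_round_trip(self, rng):
        frame = self.frame()
        v = rng.normal(size=3) * 5
        assert np.abs(vector_from_frame(frame, vector_in_frame(frame, v))
                      - v).max() < 1e-12


def test_taper_frame_rejects_nonorthonormal():
    with pytest.raises(InputError):
        TaperFrame(origin=np.zeros(3), X=[1.0, 0, 0], Y=[1.0, 0, 0],
                   Z=[0.0, 0, 1.0])
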