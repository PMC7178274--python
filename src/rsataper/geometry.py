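"""Uniplanar stereo X-ray imaging geometry.

Central projection onto a film plane at z=0, two-plane calibration-box
calibration of each view (film mapping + focus recovery), and 3D
triangulation of stereo correspondences.

Conventions: the global frame is the calibration-box frame — +x medial,
+y cranial, +z anterior for a right hip; the film lies in z=0 and both
X-ray foci are at positive z. All lengths in mm, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import (
    DegenerateGeometryError,
    IllConditionedError,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "SceneGeometry",
    "CalibrationBoxModel",
    "AffineMap2D",
    "ViewCalibration",
    "ReconstructedPoint",
    "project_point",
    "project_points",
    "calibrate_view",
    "reconstruct_point",
]

_ANGLE_TOL_DEG = 1e-9


def _as_points(a, dim: int, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != dim:
        raise InputError(f"{name} must be an (n, {dim}) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def _rank_of_spread(points: np.ndarray, rtol: float = 1e-8) -> int:
    """Affine rank of a point cloud (0 = coincident, 1 = collinear, 2 = coplanar...)."""
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > rtol * s[0]))


@dataclass(frozen=True)
class SceneGeometry:
    """Two-focus uniplanar RSA scene; the film plane is z=0 of the global frame."""

    foci: np.ndarray                    # (2, 3) focus positions, mm
    beam_intersection_angle: float      # degrees, between the two central rays
    film_focus_distance: float          # mm
    box_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        foci = _as_points(self.foci, 3, "foci")
        if foci.shape[0] != 2:
            raise InputError("exactly two foci required")
        object.__setattr__(self, "foci", foci)
        object.__setattr__(self, "box_center", np.asarray(self.box_center, dtype=float))
        if np.any(foci[:, 2] <= 0):
            raise DegenerateGeometryError("both foci must have positive z")
        rays = foci - self.box_center
        cosang = rays[0] @ rays[1] / (np.linalg.norm(rays[0]) * np.linalg.norm(rays[1]))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if abs(angle - self.beam_intersection_angle) > _ANGLE_TOL_DEG:
            raise DegenerateGeometryError(
                f"central rays intersect at {angle:.12f}°, expected "
                f"{self.beam_intersection_angle}°"
            )

    @classmethod
    def default(cls, film_focus_distance: float = 1400.0,
                beam_intersection_angle: float = 40.0) -> "SceneGeometry":
        """Symmetric setup: foci at z = film_focus_distance, offset along ±x so the
        central rays towards the box center (origin) intersect at the given angle."""
        half = np.radians(beam_intersection_angle / 2.0)
        dx = film_focus_distance * np.tan(half)
        foci = np.array([[-dx, 0.0, film_focus_distance],
                         [+dx, 0.0, film_focus_distance]])
        return cls(foci=foci, beam_intersection_angle=beam_intersection_angle,
                   film_focus_distance=film_focus_distance)


@dataclass(frozen=True)
class CalibrationBoxModel:
    """Two-plane calibration box: fiducial markers in the film plane (z=0) and
    control markers in an elevated plane (z = control_height)."""

    fiducial_markers: np.ndarray   # (F, 3), all z == 0
    control_markers: np.ndarray    # (C, 3), all z == control_height
    control_height: float          # mm

    def __post_init__(self):
        fid = _as_points(self.fiducial_markers, 3, "fiducial_markers")
        ctl = _as_points(self.control_markers, 3, "control_markers")
        object.__setattr__(self, "fiducial_markers", fid)
        object.__setattr__(self, "control_markers", ctl)
        if np.any(np.abs(fid[:, 2]) > 1e-9):
            raise InputError("fiducial markers must lie in the film plane z=0")
        if np.any(np.abs(ctl[:, 2] - self.control_height) > 1e-9):
            raise InputError("control markers must lie at z = control_height")

    def validate(self) -> None:
        """Raise if the layout cannot support a calibration."""
        if self.fiducial_markers.shape[0] < 4:
            raise InsufficientDataError("need at least 4 fiducial markers")
        if self.control_markers.shape[0] < 4:
            raise InsufficientDataError("need at least 4 control markers")
        if _rank_of_spread(self.fiducial_markers[:, :2]) < 2:
            raise IllConditionedError("fiducial markers are collinear or coincident")
        if _rank_of_spread(self.control_markers[:, :2]) < 2:
            raise IllConditionedError("control markers are collinear or coincident")

    @classmethod
    def default_grid(cls, fiducial_pitch: float = 60.0, control_pitch: float = 55.0,
                     control_height: float = 80.0, n: int = 3) -> "CalibrationBoxModel":
        """Synthetic n×n two-plane layout (any non-degenerate layout works)."""
        idx = np.arange(n) - (n - 1) / 2.0
        gx, gy = np.meshgrid(idx, idx, indexing="xy")
        fid = np.column_stack([gx.ravel() * fiducial_pitch,
                               gy.ravel() * fiducial_pitch,
                               np.zeros(n * n)])
        ctl = np.column_stack([gx.ravel() * control_pitch,
                               gy.ravel() * control_pitch,
                               np.full(n * n, float(control_height))])
        return cls(fiducial_markers=fid, control_markers=ctl,
                   control_height=float(control_height))


@dataclass(frozen=True)
class AffineMap2D:
    """Planar affine map u -> A u + b from digitized to film-plane coordinates."""

    A: np.ndarray  # (2, 2)
    b: np.ndarray  # (2,)

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ np.asarray(self.A, float).T + np.asarray(self.b, float)
        return out[0] if np.asarray(points).ndim == 1 else out

    @classmethod
    def identity(cls) -> "AffineMap2D":
        return cls(A=np.eye(2), b=np.zeros(2))

    @classmethod
    def fit(cls, src: np.ndarray, dst: np.ndarray) -> "AffineMap2D":
        """Least-squares affine map with src -> dst (n >= 3 non-collinear)."""
        src = _as_points(src, 2, "src")
        dst = _as_points(dst, 2, "dst")
        if src.shape != dst.shape:
            raise InputError("src/dst count mismatch")
        if src.shape[0] < 3 or _rank_of_spread(src) < 2:
            raise InsufficientDataError("affine fit needs >=3 non-collinear points")
        design = np.column_stack([src, np.ones(src.shape[0])])
        coeff, *_ = np.linalg.lstsq(design, dst, rcond=None)
        return cls(A=coeff[:2].T.copy(), b=coeff[2].copy())


@dataclass(frozen=True)
class ViewCalibration:
    """One view's recovered film mapping, focus position and quality numbers."""

    film_transform: AffineMap2D
    focus_position: np.ndarray  # (3,), mm
    calibration_error: float    # RMS fiducial residual after mapping, mm
    focus_error: float          # RMS point-to-ray distance of the focus, mm

    def __post_init__(self):
        object.__setattr__(self, "focus_position",
                           np.asarray(self.focus_position, dtype=float))
        if self.calibration_error < 0 or self.focus_error < 0:
            raise InputError("error metrics must be non-negative")
        if self.focus_position[2] <= 0:
            raise DegenerateGeometryError("focus must be above the film plane (z > 0)")

    def map_to_film(self, points_2d) -> np.ndarray:
        """Digitized 2D -> film-plane 3D point(s) (embedded at z=0)."""
        mapped = np.atleast_2d(self.film_transform.apply(points_2d))
        out = np.column_stack([mapped, np.zeros(mapped.shape[0])])
        return out[0] if np.asarray(points_2d).ndim == 1 else out


@dataclass(frozen=True)
class ReconstructedPoint:
    """Triangulated 3D point with the ray-crossing quality number."""

    position: np.ndarray      # (3,), mm
    crossing_distance: float  # mm, shortest distance between the two rays

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.crossing_distance < 0:
            raise InputError("crossing_distance must be >= 0")


def project_points(geometry: SceneGeometry, focus_index: int, points) -> np.ndarray:
    """Central projection of 3D point(s) through focus `focus_index` (1 or 2)
    onto the film plane z=0. Returns 2D film coordinates (mm)."""
    if focus_index not in (1, 2):
        raise InputError("focus_index must be 1 or 2")
    focus = geometry.foci[focus_index - 1]
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise InputError("points must be 3D")
    dz = focus[2] - pts[:, 2]
    if np.any(dz <= 0):
        raise DegenerateGeometryError("point at or above focus height cannot project")
    t = (focus[2] / dz)[:, None]
    film = focus[None, :2] + t * (pts[:, :2] - focus[None, :2])
    return film[0] if np.asarray(points).ndim == 1 else film


def project_point(geometry: SceneGeometry, focus_index: int, point) -> np.ndarray:
    """Single-point convenience wrapper around :func:`project_points`."""
    return project_points(geometry, focus_index, np.asarray(point, dtype=float))


def _nearest_point_to_rays(origins: np.ndarray, directions: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares point minimizing summed squared distance to a set of rays.

    Returns (point, per-ray perpendicular distances). Raises IllConditionedError
    when the rays do not constrain a point (parallel / coincident rays)."""
    d = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    # sum_i (I - d_i d_i^T) x = sum_i (I - d_i d_i^T) o_i
    proj = np.eye(3)[None, :, :] - d[:, :, None] * d[:, None, :]
    lhs = proj.sum(axis=0)
    rhs = np.einsum("nij,nj->i", proj, origins)
    w = np.linalg.eigvalsh(lhs)
    if w[0] < 1e-10 * max(w[-1], 1.0):
        raise IllConditionedError("rays are near-parallel; intersection point undefined")
    x = np.linalg.solve(lhs, rhs)
    rel = x[None, :] - origins
    perp = rel - (np.einsum("ni,ni->n", rel, d))[:, None] * d
    return x, np.linalg.norm(perp, axis=1)


def calibrate_view(box: CalibrationBoxModel, observed_fiducials, observed_controls
                   ) -> ViewCalibration:
    """Calibrate one X-ray view from digitized calibration-box observations.

    The film mapping is the least-squares planar affine fitted on the fiducials;
    the focus is the least-squares intersection of the rays joining each control
    marker's known 3D position to its mapped film image. Correspondence is by
    index and counts must match the box model.
    """
    obs_fid = _as_points(observed_fiducials, 2, "observed_fiducials")
    obs_ctl = _as_points(observed_controls, 2, "observed_controls")
    box.validate()
    if obs_fid.shape[0] != box.fiducial_markers.shape[0]:
        raise InputError("fiducial observation count does not match the box model")
    if obs_ctl.shape[0] != box.control_markers.shape[0]:
        raise InputError("control observation count does not match the box model")

    film_map = AffineMap2D.fit(obs_fid, box.fiducial_markers[:, :2])
    resid = film_map.apply(obs_fid) - box.fiducial_markers[:, :2]
    calibration_error = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))

    film_pts = np.column_stack([film_map.apply(obs_ctl), np.zeros(obs_ctl.shape[0])])
    directions = box.control_markers - film_pts
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms < 1e-9):
        raise DegenerateGeometryError("control marker coincides with its film image")
    focus, dists = _nearest_point_to_rays(film_pts, directions)
    focus_error = float(np.sqrt(np.mean(dists ** 2)))
    return ViewCalibration(film_transform=film_map, focus_position=focus,
                           calibration_error=calibration_error,
                           focus_error=focus_error)


def reconstruct_point(cal1: ViewCalibration, cal2: ViewCalibration,
                      image1, image2) -> ReconstructedPoint:
    """Triangulate a stereo correspondence: midpoint of the common perpendicular
    of the two back-projected rays, plus the ray-crossing distance."""
    p1 = cal1.map_to_film(np.asarray(image1, dtype=float))
    p2 = cal2.map_to_film(np.asarray(image2, dtype=float))
    o1, o2 = cal1.focus_position, cal2.focus_position
    d1 = p1 - o1
    d2 = p2 - o2
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    cross = np.cross(d1, d2)
    denom = cross @ cross
    if denom < 1e-24:
        raise DegenerateGeometryError("back-projected rays are parallel")
    w = o2 - o1
    t1 = np.cross(w, d2) @ cross / denom
    t2 = np.cross(w, d1) @ cross / denom
    q1 = o1 + t1 * d1
    q2 = o2 + t2 * d2
    return ReconstructedPoint(position=(q1 + q2) / 2.0,
                              crossing_distance=float(np.linalg.norm(q1 - q2)))
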