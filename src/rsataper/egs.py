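"""Elementary-geometrical-shape (EGS) pose recovery.

Sphere center from silhouette contours (known radius), cone/taper axis from
silhouette lines, virtual-marker construction for the stem rigid body, and
the taper coordinate frame used to express head-taper migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._exceptions import (
    ConvergenceError,
    DegenerateGeometryError,
    InputError,
    InsufficientDataError,
)
from .geometry import ViewCalibration

__all__ = [
    "SphereModel",
    "ConeModel",
    "VirtualMarkerSet",
    "TaperFrame",
    "fit_sphere_center",
    "fit_cone_axis",
    "construct_virtual_markers",
    "build_taper_frame",
    "vector_in_frame",
    "vector_from_frame",
]

#: Below this half-angle (degrees) a fitted cone is treated as a cylinder.
CYLINDER_HALF_ANGLE_DEG = 0.1


def _unit(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InputError(f"{name} has zero length")
    return v / n


@dataclass(frozen=True)
class SphereModel:
    center: np.ndarray  # (3,) mm
    radius: float       # mm, known and fixed

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise InputError("sphere radius must be positive")


@dataclass(frozen=True)
class ConeModel:
    axis_point: np.ndarray      # apex, mm
    axis_direction: np.ndarray  # unit vector, cone opens along +direction
    half_angle: float           # degrees, in (0, 90)

    def __post_init__(self):
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, float))
        object.__setattr__(self, "axis_direction",
                           _unit(self.axis_direction, "axis_direction"))
        if not 0.0 <= self.half_angle < 90.0:
            raise InputError("half_angle must be in [0, 90) degrees")

    @property
    def is_cylindrical(self) -> bool:
        return self.half_angle < CYLINDER_HALF_ANGLE_DEG


@dataclass(frozen=True)
class VirtualMarkerSet:
    """Three constructed stem points: head center (P1), stem tip (P2) and the
    orthogonal projection of P1 onto the stem-cylinder axis (P3)."""

    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    reference_point: np.ndarray  # centroid of P1-P3
    collinear: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.vstack([self.P1, self.P2, self.P3])


@dataclass(frozen=True)
class TaperFrame:
    """Right-handed orthonormal frame: Y along the taper axis, X in the
    implant-marker plane pointing medially, Z = X × Y (anterior)."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        for name in ("origin", "X", "Y", "Z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        M = self.matrix
        if np.max(np.abs(M.T @ M - np.eye(3))) > 1e-9:
            raise InputError("frame axes are not orthonormal")
        if np.linalg.det(M) < 0:
            raise InputError("frame is left-handed")

    @property
    def matrix(self) -> np.ndarray:
        """Columns are X, Y, Z (frame -> global rotation)."""
        return np.column_stack([self.X, self.Y, self.Z])


def _contour_rays(cal: ViewCalibration, contour) -> tuple[np.ndarray, np.ndarray]:
    film = cal.map_to_film(np.asarray(contour, dtype=float))
    focus = cal.focus_position
    dirs = film - focus
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    return np.broadcast_to(focus, dirs.shape).copy(), dirs


def _initial_sphere_center(focus: np.ndarray, dirs: np.ndarray, radius: float
                           ) -> np.ndarray:
    # The silhouette rays form a viewing cone tangent to the sphere: every ray
    # direction d satisfies d·axis = cos(half-angle). Solve the homogeneous
    # system [d_i | -1] @ [axis; cos(half)] = 0; the center then lies on the
    # axis at distance radius / sin(half-angle) from the focus. Exact for
    # noiseless data, full conics and partial arcs alike.
    M = np.column_stack([dirs, -np.ones(dirs.shape[0])])
    _, _, vt = np.linalg.svd(M)
    v = vt[-1]
    if v[3] < 0:
        v = -v
    axis = _unit(v[:3], "silhouette cone axis")
    cos_half = float(np.clip(v[3] / np.linalg.norm(v[:3]), -1.0, 1.0))
    sin_half = np.sqrt(max(1.0 - cos_half ** 2, 0.0))
    if sin_half < 1e-9:
        raise DegenerateGeometryError("silhouette rays have no angular spread")
    return focus + axis * (radius / sin_half)


def fit_sphere_center(cals: Sequence[ViewCalibration], contours: Sequence,
                      radius: float, min_points: int = 8
                      ) -> tuple[np.ndarray, float]:
    """Recover the center of a sphere of known radius from silhouette contours.

    Each digitized contour point back-projects to a ray tangent to the sphere,
    so the center minimizes sum_i (dist(center, ray_i) - radius)^2 over all
    views (1 or 2). Returns (center, rms residual in mm).
    """
    if radius <= 0:
        raise InputError("radius must be positive")
    if len(cals) != len(contours) or not 1 <= len(cals) <= 2:
        raise InputError("need 1-2 views with one contour per view")
    counts = [np.asarray(c).shape[0] for c in contours]
    if all(c < min_points for c in counts):
        raise InsufficientDataError(
            f"every view has fewer than {min_points} silhouette points")
    origins, dirs = [], []
    for cal, contour in zip(cals, contours):
        o, d = _contour_rays(cal, contour)
        origins.append(o)
        dirs.append(d)
    best = int(np.argmax(counts))
    x0 = _initial_sphere_center(origins[best][0], dirs[best], radius)
    o = np.vstack(origins)
    d = np.vstack(dirs)

    def residuals(c):
        rel = c[None, :] - o
        along = np.einsum("ni,ni->n", rel, d)
        perp = rel - along[:, None] * d
        return np.linalg.norm(perp, axis=1) - radius

    sol = least_squares(residuals, x0, method="lm")
    if not sol.success:
        raise ConvergenceError("sphere fit did not converge",
                               diagnostics={"status": sol.status,
                                            "message": sol.message,
                                            "cost": float(sol.cost)})
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return sol.x.copy(), rms


def _silhouette_planes(cals: Sequence[ViewCalibration], silhouette_lines: Sequence
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Unit normals and offsets of the planes spanned by each view's focus and
    each silhouette line segment (both of which are tangent to the cone)."""
    normals, offsets = [], []
    for cal, lines in zip(cals, silhouette_lines):
        focus = cal.focus_position
        for seg in np.asarray(lines, dtype=float):
            e1 = cal.map_to_film(seg[0])
            e2 = cal.map_to_film(seg[1])
            n = np.cross(e1 - focus, e2 - focus)
            norm = np.linalg.norm(n)
            if norm < 1e-9:
                raise DegenerateGeometryError(
                    "silhouette segment is degenerate (endpoints on one ray)")
            n = n / norm
            normals.append(n)
            offsets.append(n @ focus)
    return np.asarray(normals), np.asarray(offsets)


def fit_cone_axis(cals: Sequence[ViewCalibration], silhouette_lines: Sequence
                  ) -> ConeModel:
    """Fit a cone (taper) from two silhouette line segments per view.

    Each segment together with its view's focus spans a plane tangent to the
    cone, giving per plane: n·a = sin(half_angle) (axis constraint) and
    n·apex = offset (incidence). The axis/half-angle come from the null vector
    of the stacked homogeneous system, then everything is polished by a joint
    least squares. A near-zero half-angle means the shape is cylindrical.
    """
    if len(cals) != len(silhouette_lines):
        raise InputError("one set of silhouette lines per calibration required")
    normals, offsets = _silhouette_planes(cals, silhouette_lines)
    if normals.shape[0] < 3:
        raise InsufficientDataError("need at least 3 tangent planes")

    # Initial axis: direction most nearly orthogonal to all normals.
    _, s_n, vt_n = np.linalg.svd(normals)
    a0 = vt_n[-1]
    if s_n[-2] < 1e-9 * s_n[0]:
        raise DegenerateGeometryError("tangent planes near-parallel (degenerate view)")
    signs = np.where(normals @ a0 < 0, -1.0, 1.0)
    n_or = normals * signs[:, None]
    d_or = offsets * signs

    # Homogeneous system [n_i | -1] @ [a; sin(half)] = 0, |a| = 1.
    M = np.column_stack([n_or, -np.ones(n_or.shape[0])])
    _, s_m, vt_m = np.linalg.svd(M)
    v = vt_m[-1]
    if s_m[-2] < 1e-12 * max(s_m[0], 1.0):
        raise DegenerateGeometryError("cone axis is not constrained by the views")
    if v[3] < 0 or (abs(v[3]) < 1e-15 and v[:3] @ a0 < 0):
        v = -v
    a = _unit(v[:3], "cone axis")
    sin_half = float(np.clip(v[3] / np.linalg.norm(v[:3]), 0.0, 1.0))

    apex, *_ = np.linalg.lstsq(n_or, d_or, rcond=None)

    scale = 100.0  # mm; balances distance residuals against angular ones

    def residuals(x):
        norm = np.linalg.norm(x[:3])
        ax = x[:3] / norm
        return np.concatenate([
            n_or @ ax - x[6],
            (n_or @ x[3:6] - d_or) / scale,
            [norm - 1.0],  # fixes the scale gauge of the axis parametrization
        ])

    x0 = np.concatenate([a, apex, [sin_half]])
    sol = least_squares(residuals, x0, method="lm")
    if sol.success:
        a = _unit(sol.x[:3], "cone axis")
        apex = sol.x[3:6]
        sin_half = float(np.clip(sol.x[6], 0.0, 1.0))
    half_angle = float(np.degrees(np.arcsin(sin_half)))
    return ConeModel(axis_point=apex, axis_direction=a, half_angle=half_angle)


def construct_virtual_markers(head_center, axis_point, axis_direction, stem_tip
                              ) -> VirtualMarkerSet:
    """Build the stem's three virtual markers.

    P1 = head center, P2 = stem tip, P3 = orthogonal projection of P1 onto the
    stem-cylinder axis line; the reference point is their centroid. The set is
    flagged collinear when the head center lies (numerically) on the axis.
    """
    p1 = np.asarray(head_center, dtype=float)
    p2 = np.asarray(stem_tip, dtype=float)
    q = np.asarray(axis_point, dtype=float)
    a = _unit(axis_direction, "cylinder axis")
    p3 = q + ((p1 - q) @ a) * a
    spread = np.vstack([p1, p2, p3])
    centered = spread - spread.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    collinear = s[1] <= 1e-9 * max(s[0], 1e-12)
    return VirtualMarkerSet(P1=p1, P2=p2, P3=p3,
                            reference_point=spread.mean(axis=0),
                            collinear=bool(collinear))


def _marker_plane_normal(markers: np.ndarray) -> np.ndarray:
    centered = markers - markers.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] <= 1e-9 * max(s[0], 1e-12):
        raise DegenerateGeometryError("implant markers are collinear")
    return vt[-1]


def build_taper_frame(cone: ConeModel, implant_markers, side: str = "right"
                      ) -> TaperFrame:
    """Taper coordinate frame: Y along the cone axis signed cranially (+global
    y), X = n × Y (n = implant-marker plane normal) signed medially, Z = X × Y.
    `side` resolves the medial direction (+x for right hips, -x for left)."""
    if side not in ("left", "right"):
        raise InputError("side must be 'left' or 'right'")
    markers = np.asarray(implant_markers, dtype=float)
    if markers.shape != (3, 3):
        raise InputError("exactly 3 implant markers required")
    Y = cone.axis_direction.copy()
    if Y[1] < 0:
        Y = -Y
    n = _marker_plane_normal(markers)
    X = np.cross(n, Y)
    if np.linalg.norm(X) < 1e-9:
        raise DegenerateGeometryError(
            "cone axis parallel to the implant-marker plane normal")
    X = X / np.linalg.norm(X)
    medial_sign = 1.0 if side == "right" else -1.0
    if X[0] * medial_sign < 0:
        X = -X
    Z = np.cross(X, Y)
    return TaperFrame(origin=cone.axis_point.copy(), X=X, Y=Y, Z=Z)


def vector_in_frame(frame: TaperFrame, v) -> np.ndarray:
    """Components of a global vector in the taper frame (norm preserving)."""
    return frame.matrix.T @ np.asarray(v, dtype=float)


def vector_from_frame(frame: TaperFrame, components) -> np.ndarray:
    """Inverse of :func:`vector_in_frame`."""
    return frame.matrix @ np.asarray(components, dtype=float)
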