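"""Rigid-body migration kinematics.

SVD point registration, RSA quality numbers (condition number, rigid-body
error), z·y·x Euler decomposition, migration of a reference point and the
reference-point correction that re-expresses a translation result at a
different reference point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ConsistencyError, DegenerateGeometryError, InputError

__all__ = [
    "RigidTransform",
    "MigrationSixDoF",
    "RigidBodyQuality",
    "EulerAngles",
    "fit_rigid_body",
    "condition_number",
    "euler_angles",
    "rotation_from_euler",
    "migration_of_point",
    "correct_reference_point",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray     # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,) mm

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise InputError("rotation must be 3x3 and translation length 3")
        if np.max(np.abs(R.T @ R - np.eye(3))) > _ORTHO_TOL:
            raise InputError("rotation matrix is not orthogonal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise InputError("rotation matrix must be proper (det = +1)")

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)

    def then(self, other: "RigidTransform") -> "RigidTransform":
        """Composition other∘self: first apply self, then other."""
        return RigidTransform(rotation=other.rotation @ self.rotation,
                              translation=other.rotation @ self.translation
                              + other.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    @classmethod
    def from_euler_translation(cls, rx: float, ry: float, rz: float,
                               translation=(0.0, 0.0, 0.0),
                               degrees: bool = True) -> "RigidTransform":
        return cls(rotation=rotation_from_euler(rx, ry, rz, degrees=degrees),
                   translation=np.asarray(translation, dtype=float))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying b first, then a."""
    return b.then(a)


@dataclass(frozen=True)
class MigrationSixDoF:
    """Six degree-of-freedom migration: translations of the reference point (mm)
    and z·y·x Euler rotations (degrees)."""

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    reference_point: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "reference_point",
                           np.asarray(self.reference_point, dtype=float))
        vals = [self.tx, self.ty, self.tz, self.rx, self.ry, self.rz]
        if not np.all(np.isfinite(vals)):
            raise InputError("migration components must be finite")

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])


@dataclass(frozen=True)
class RigidBodyQuality:
    """Marker-configuration condition number and rigid-body fit error."""

    condition_number: float
    rigid_body_error: float

    def __post_init__(self):
        if self.condition_number < 0 or self.rigid_body_error < 0:
            raise InputError("quality metrics must be >= 0")


@dataclass(frozen=True)
class EulerAngles:
    """z·y·x Euler decomposition in degrees; iterates as (rx, ry, rz)."""

    rx: float
    ry: float
    rz: float
    gimbal_adjacent: bool = field(default=False, compare=False)

    def __iter__(self):
        return iter((self.rx, self.ry, self.rz))


def _check_points(points, min_n: int, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"{name} must be an (n, 3) array")
    if pts.shape[0] < min_n:
        raise InputError(f"{name} needs at least {min_n} points")
    if not np.all(np.isfinite(pts)):
        raise InputError(f"{name} contains non-finite values")
    return pts


def fit_rigid_body(ref_points, fu_points) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration mapping ref_points onto fu_points.

    Kabsch/SVD solution on the cross-covariance of the centered clouds, with
    the reflection corrected to det = +1. Returns the transform and the RMS
    residual after applying it (the rigid-body error, mm).
    """
    ref = _check_points(ref_points, 3, "ref_points")
    fu = _check_points(fu_points, 3, "fu_points")
    if ref.shape != fu.shape:
        raise InputError("ref and follow-up point counts must match")
    c_ref = ref.mean(axis=0)
    c_fu = fu.mean(axis=0)
    ref0 = ref - c_ref
    fu0 = fu - c_fu
    s_ref = np.linalg.svd(ref0, compute_uv=False)
    if s_ref[1] <= 1e-8 * max(s_ref[0], 1e-12):
        raise DegenerateGeometryError("reference points are collinear")
    H = ref0.T @ fu0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = c_fu - R @ c_ref
    resid = ref @ R.T + t - fu
    rbe = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t), rbe


def condition_number(points) -> float:
    """Marker-configuration condition number CN = 100 / sigma_2 where sigma_2 is
    the middle singular value (mm) of the centroid-centered configuration.
    Collinear sets return +inf (rotation about the line is unobservable)."""
    pts = _check_points(points, 3, "points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1e-12):
        return float("inf")
    return 100.0 / float(s[1])


def rotation_from_euler(rx: float, ry: float, rz: float, degrees: bool = True
                        ) -> np.ndarray:
    """Rotation matrix R = Rz·Ry·Rx (x applied first)."""
    if degrees:
        rx, ry, rz = np.radians([rx, ry, rz])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


_GIMBAL_MARGIN_DEG = 1.0


def euler_angles(transform: RigidTransform) -> EulerAngles:
    """Decompose R = Rz·Ry·Rx into degrees. Gimbal-adjacent cases (|ry| within
    1° of 90°) are flagged and additionally warned about."""
    R = transform.rotation
    sy = -R[2, 0]
    sy = float(np.clip(sy, -1.0, 1.0))
    ry = np.arcsin(sy)
    gimbal = abs(abs(np.degrees(ry)) - 90.0) < _GIMBAL_MARGIN_DEG
    if gimbal:
        warnings.warn("Euler decomposition near gimbal lock (|Ry| ~ 90°)",
                      RuntimeWarning, stacklevel=2)
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    else:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    return EulerAngles(rx=float(np.degrees(rx)), ry=float(np.degrees(ry)),
                       rz=float(np.degrees(rz)), gimbal_adjacent=bool(gimbal))


def migration_of_point(transform: RigidTransform, point) -> np.ndarray:
    """Displacement of a reference point: d(p) = R p + t - p (mm)."""
    p = np.asarray(point, dtype=float)
    return transform.rotation @ p + transform.translation - p


_CONSISTENCY_TOL = 1e-6


def correct_reference_point(transform: RigidTransform, migration_at_old,
                            old_point, new_point) -> np.ndarray:
    """Re-express a translational migration result at a new reference point:

        d(new) = d(old) + (R - I)(new - old)

    `migration_at_old` must be consistent with the transform at `old_point`
    (checked within 1e-6 mm). Equivalent to migration_of_point(transform, new).
    """
    d_old = np.asarray(migration_at_old, dtype=float)
    old = np.asarray(old_point, dtype=float)
    new = np.asarray(new_point, dtype=float)
    expected = migration_of_point(transform, old)
    if np.linalg.norm(expected - d_old) > _CONSISTENCY_TOL:
        raise ConsistencyError(
            "migration_at_old disagrees with the transform at old_point "
            f"(|Δ| = {np.linalg.norm(expected - d_old):.3e} mm)")
    return d_old + (transform.rotation - np.eye(3)) @ (new - old)
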