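"""Synthetic RSA phantom studies with paired ground truth.

Generates a cohort of virtual patients in a uniplanar two-focus setup:
a stem rigid body (3 tantalum markers, taper cone, shaft cylinder, tip),
a spherical ball head, bone markers, a follow-up schedule, implant-to-bone
migration trajectories, head-taper slip trajectories expressed in the taper
frame, patient repositioning between visits, and i.i.d. Gaussian digitizing
noise on every 2D film coordinate. Every generated exam is paired with the
exact ground truth that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, field_validator, model_validator

from ._exceptions import DegenerateGeometryError, InputError
from .egs import ConeModel, TaperFrame, build_taper_frame
from .geometry import (
    CalibrationBoxModel,
    SceneGeometry,
    project_points,
)
from .io import (
    EXAM_SCHEMA,
    TRUTH_SCHEMA,
    Exam,
    ViewObservations,
    config_hash,
    save_exam,
    save_json,
    box_to_dict,
    scene_to_dict,
    transform_to_dict,
    visit_token,
)
from .kinematics import RigidTransform, rotation_from_euler

__all__ = [
    "PhantomConfig",
    "StemTruth",
    "VisitTruth",
    "PatientTruth",
    "PhantomStudy",
    "default_slip_trajectory",
    "trajectory_fractions",
    "inject_patient_variation",
    "generate_study",
    "write_study",
]

DEFAULT_SCHEDULE = (0.0, 1.5, 3.0, 6.0, 12.0, 24.0, 60.0, 120.0)

#: Declared three-phase fraction table (slow 0-6 mo, fast 6-24 mo, plateau)
#: anchored at the default follow-up schedule; interpolated for other schedules.
THREE_PHASE_ANCHORS = (
    (0.0, 0.00), (1.5, 0.05), (3.0, 0.10), (6.0, 0.20),
    (12.0, 0.60), (24.0, 0.90), (60.0, 0.97), (120.0, 1.00),
)

HEAD_NECK_LENGTHS = {"S": 42.0, "M": 45.0, "L": 48.0}


class PhantomConfig(BaseModel):
    """Everything needed to generate a deterministic synthetic study."""

    # Scene / calibration box
    film_focus_distance: float = 1400.0
    beam_intersection_angle: float = 40.0
    fiducial_pitch: float = 60.0
    control_pitch: float = 55.0
    control_height: float = 80.0

    # Schedule and implant
    schedule_months: tuple[float, ...] = DEFAULT_SCHEDULE
    head_radius: float = 14.0              # 28 mm ball head
    taper_half_angle: float = 2.8055       # deg; taper angle 5.611 deg
    neck_shaft_angle: float = 126.0        # deg, caput-collum-diaphyseal
    side: Literal["left", "right"] = "right"
    n_contour_points: int = 48

    # Cohort
    n_patients: int = 1
    head_neck_mix: dict[str, int] | None = None  # counts per S/M/L; None = thirds

    # Trajectories (totals reached at the last scheduled visit)
    total_migration_translation: tuple[float, float, float] = (0.0, -0.5, 0.0)
    total_migration_rotation: tuple[float, float, float] = (0.0, 0.0, -1.0)
    migration_pattern: Literal["three_phase", "linear", "zero"] = "three_phase"
    total_slip: tuple[float, float, float] = (0.0, 0.0, 0.0)  # taper frame, mm
    slip_pattern: Literal["three_phase", "linear", "zero"] = "three_phase"

    # Noise and per-patient variation
    noise_sigma_2d: float = 0.0     # mm, on every anatomical 2D observation
    noise_sigma_cal: float = 0.0    # mm, on calibration-box observations
    marker_jitter_sigma: float = 0.0   # mm, per-patient marker placement
    amplitude_sigma: float = 0.0       # lognormal sigma of trajectory amplitudes
    repositioning_translation: float = 8.0  # mm, uniform half-range per axis
    repositioning_rotation: float = 2.0     # deg, uniform half-range per axis

    anatomy_offset: tuple[float, float, float] = (0.0, 0.0, 150.0)
    seed: int = 0

    @field_validator("schedule_months")
    @classmethod
    def _schedule_ok(cls, v):
        if len(v) < 1 or v[0] != 0.0:
            raise ValueError("schedule must start at month 0 (reference visit)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("schedule months must be strictly increasing")
        return v

    @field_validator("noise_sigma_2d", "noise_sigma_cal", "marker_jitter_sigma",
                     "amplitude_sigma")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("sigmas must be >= 0")
        return v

    @model_validator(mode="after")
    def _geometry_ok(self):
        if self.head_radius <= 0 or not 0 < self.taper_half_angle < 90:
            raise ValueError("degenerate implant geometry")
        if self.film_focus_distance <= self.anatomy_offset[2]:
            raise ValueError("anatomy must sit below the foci")
        if self.head_neck_mix is not None:
            if sum(self.head_neck_mix.values()) != self.n_patients:
                raise ValueError("head_neck_mix counts must sum to n_patients")
            if set(self.head_neck_mix) - set(HEAD_NECK_LENGTHS):
                raise ValueError("head_neck_mix keys must be S/M/L")
        return self

    def scene(self) -> SceneGeometry:
        return SceneGeometry.default(self.film_focus_distance,
                                     self.beam_intersection_angle)

    def box(self) -> CalibrationBoxModel:
        return CalibrationBoxModel.default_grid(self.fiducial_pitch,
                                                self.control_pitch,
                                                self.control_height)


def trajectory_fractions(schedule: Sequence[float], pattern: str) -> np.ndarray:
    """Fraction of the total trajectory reached at each scheduled visit."""
    months = np.asarray(schedule, dtype=float)
    if pattern == "zero":
        return np.zeros_like(months)
    if pattern == "linear":
        last = months[-1] if months[-1] > 0 else 1.0
        return months / last
    if pattern == "three_phase":
        anchors = np.asarray(THREE_PHASE_ANCHORS)
        return np.interp(months, anchors[:, 0], anchors[:, 1])
    raise InputError(f"unknown trajectory pattern: {pattern!r}")


def default_slip_trajectory(total_slip, pattern: str,
                            schedule: Sequence[float] = DEFAULT_SCHEDULE
                            ) -> np.ndarray:
    """Per-visit head-taper slip vectors (taper-frame mm), one row per visit."""
    total = np.asarray(total_slip, dtype=float)
    if total.shape != (3,):
        raise InputError("total_slip must be a 3-vector")
    frac = trajectory_fractions(schedule, pattern)
    return frac[:, None] * total[None, :]


@dataclass
class StemTruth:
    """Stem geometry in the bone (reference) frame."""

    implant_markers: np.ndarray  # (3, 3) tantalum markers
    shaft_point: np.ndarray      # point on the stem-cylinder axis
    shaft_direction: np.ndarray  # unit, cranial
    tip: np.ndarray              # lowest point of the tip (on the shaft axis)
    cone: ConeModel              # taper; apex with opening direction
    taper_s_range: tuple[float, float]  # visible ruling range from apex, mm
    head_center: np.ndarray      # seated head center (no slip)
    head_radius: float


@dataclass
class VisitTruth:
    months: float
    migration: RigidTransform   # implant-to-bone, bone frame
    slip: np.ndarray            # (3,) taper-frame mm, head relative to stem
    pose: RigidTransform        # bone frame -> world (patient position)


@dataclass
class PatientTruth:
    patient_id: str
    group: str                  # head-neck length S/M/L
    stem: StemTruth
    bone_markers: np.ndarray
    taper_frame: TaperFrame     # built from true cone + markers, bone frame
    amp_migration: float
    amp_slip: float
    visits: list[VisitTruth]

    def head_center_at(self, visit: VisitTruth) -> np.ndarray:
        """True head center in the bone frame, including slip."""
        return self.stem.head_center + self.taper_frame.matrix @ visit.slip


@dataclass
class PhantomStudy:
    config: PhantomConfig
    scene: SceneGeometry
    box: CalibrationBoxModel
    patients: list[PatientTruth]
    exams: dict[str, dict[float, Exam]] = field(default_factory=dict)


def _base_stem(head_neck_length: float, cfg: PhantomConfig) -> StemTruth:
    """Template stem in the bone frame: shaft along +y, neck tilted medially."""
    tilt = np.radians(180.0 - cfg.neck_shaft_angle)
    u = np.array([np.sin(tilt), np.cos(tilt), 0.0])  # base -> head direction
    base = np.array([0.0, -10.0, 0.0])
    head_center = base + head_neck_length * u
    apex_offset = 15.0
    apex = base + (head_neck_length + apex_offset) * u
    cone = ConeModel(axis_point=apex, axis_direction=-u,
                     half_angle=cfg.taper_half_angle)
    markers = np.array([[18.0, -25.0, 12.0],
                        [-20.0, -55.0, -10.0],
                        [6.0, -95.0, 2.0]])
    return StemTruth(
        implant_markers=markers,
        shaft_point=np.zeros(3),
        shaft_direction=np.array([0.0, 1.0, 0.0]),
        tip=np.array([0.0, -120.0, 0.0]),
        cone=cone,
        taper_s_range=(30.0, 48.0),
        head_center=head_center,
        head_radius=cfg.head_radius,
    )


_BASE_BONE_MARKERS = np.array([
    [30.0, 20.0, 25.0],
    [-28.0, 5.0, -15.0],
    [25.0, -60.0, -25.0],
    [-22.0, -85.0, 18.0],
    [8.0, -130.0, -20.0],
    [-5.0, -40.0, 30.0],
])


def _group_assignment(cfg: PhantomConfig) -> list[str]:
    if cfg.head_neck_mix is not None:
        out: list[str] = []
        for g in ("S", "M", "L"):
            out.extend([g] * cfg.head_neck_mix.get(g, 0))
        return out
    base, extra = divmod(cfg.n_patients, 3)
    counts = {g: base + (1 if i < extra else 0)
              for i, g in enumerate(("S", "M", "L"))}
    return [g for g in ("S", "M", "L") for _ in range(counts[g])]


def inject_patient_variation(cfg: PhantomConfig, rng: np.random.Generator,
                             group: str) -> dict:
    """Per-patient perturbations: marker placement jitter, lognormal trajectory
    amplitude multipliers (mean exactly 1), and the head-neck geometry of the
    assigned group. Everything returned is recorded in the ground truth."""
    stem = _base_stem(HEAD_NECK_LENGTHS[group], cfg)
    sig = cfg.marker_jitter_sigma
    implant_markers = stem.implant_markers + rng.normal(0.0, sig, (3, 3))
    bone_markers = _BASE_BONE_MARKERS + rng.normal(0.0, sig,
                                                   _BASE_BONE_MARKERS.shape)
    if cfg.amplitude_sigma > 0:
        mu = -0.5 * cfg.amplitude_sigma ** 2
        amp_mig = float(np.exp(rng.normal(mu, cfg.amplitude_sigma)))
        amp_slip = float(np.exp(rng.normal(mu, cfg.amplitude_sigma)))
    else:
        amp_mig = amp_slip = 1.0
    stem.implant_markers = implant_markers
    return {"stem": stem, "bone_markers": bone_markers,
            "amp_migration": amp_mig, "amp_slip": amp_slip}


def _visit_pose(cfg: PhantomConfig, rng: np.random.Generator,
                is_reference: bool) -> RigidTransform:
    offset = np.asarray(cfg.anatomy_offset, dtype=float)
    if is_reference:
        return RigidTransform(rotation=np.eye(3), translation=offset)
    ang = rng.uniform(-cfg.repositioning_rotation, cfg.repositioning_rotation, 3)
    shift = rng.uniform(-cfg.repositioning_translation,
                        cfg.repositioning_translation, 3)
    return RigidTransform(rotation=rotation_from_euler(*ang),
                          translation=offset + shift)


def sphere_silhouette_points(focus: np.ndarray, center: np.ndarray, radius: float,
                             n: int, arc: tuple[float, float] = (0.0, 360.0)
                             ) -> np.ndarray:
    """3D points on the sphere's silhouette circle as seen from `focus`."""
    rel = center - focus
    d = np.linalg.norm(rel)
    if d <= radius:
        raise DegenerateGeometryError("focus inside the sphere")
    u = rel / d
    # Tangency circle: offset r^2/d from the center towards the focus.
    c = center - (radius ** 2 / d) * u
    rho = radius * np.sqrt(1.0 - (radius / d) ** 2)
    e1 = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(u, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    theta = np.radians(np.linspace(arc[0], arc[1], n, endpoint=False))
    return c + rho * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)


def cone_silhouette_segments(focus: np.ndarray, cone: ConeModel,
                             s_range: tuple[float, float]) -> np.ndarray:
    """The two silhouette ruling segments of a cone seen from `focus`.

    Returns a (2, 2, 3) array of 3D endpoint pairs, at ruling-arclength range
    `s_range` from the apex."""
    apex = cone.axis_point
    a = cone.axis_direction
    sin_phi = np.sin(np.radians(cone.half_angle))
    cos_phi = np.cos(np.radians(cone.half_angle))
    e = focus - apex
    e_norm = np.linalg.norm(e)
    if e_norm < 1e-9:
        raise DegenerateGeometryError("focus at the cone apex")
    e = e / e_norm
    # Tangent-plane normals: n ⟂ (focus - apex), n·a = sin(half_angle).
    u = np.cross(e, a)
    if np.linalg.norm(u) < 1e-9:
        raise DegenerateGeometryError("viewing direction along the cone axis")
    u = u / np.linalg.norm(u)
    v = np.cross(e, u)
    g, h = u @ a, v @ a
    rho2 = g * g + h * h
    if rho2 <= sin_phi ** 2:
        raise DegenerateGeometryError("focus inside the cone; no silhouette")
    alpha0 = g * sin_phi / rho2
    beta0 = h * sin_phi / rho2
    resid = np.sqrt(1.0 - sin_phi ** 2 / rho2) / np.sqrt(rho2)
    segments = []
    for sgn in (+1.0, -1.0):
        n = (alpha0 + sgn * resid * (-h)) * u + (beta0 + sgn * resid * g) * v
        n /= np.linalg.norm(n)
        ruling = (a - sin_phi * n) / cos_phi
        segments.append([apex + s_range[0] * ruling, apex + s_range[1] * ruling])
    return np.asarray(segments)


def _project_view(scene: SceneGeometry, focus_index: int, pts: np.ndarray
                  ) -> np.ndarray:
    return np.atleast_2d(project_points(scene, focus_index, pts))


def _make_exam(cfg: PhantomConfig, scene: SceneGeometry, box: CalibrationBoxModel,
               patient: PatientTruth, visit: VisitTruth,
               rng: np.random.Generator) -> Exam:
    stem = patient.stem
    world = visit.pose
    implant_world = world.apply(visit.migration.apply(stem.implant_markers))
    bone_world = world.apply(patient.bone_markers)
    tip_world = world.apply(visit.migration.apply(stem.tip))
    shaft_upper_world = world.apply(visit.migration.apply(stem.shaft_point))
    head_world = world.apply(visit.migration.apply(patient.head_center_at(visit)))
    rot = world.rotation @ visit.migration.rotation
    cone_world = ConeModel(
        axis_point=world.apply(visit.migration.apply(stem.cone.axis_point)),
        axis_direction=rot @ stem.cone.axis_direction,
        half_angle=stem.cone.half_angle,
    )
    views = []
    for idx in (1, 2):
        focus = scene.foci[idx - 1]
        contour3d = sphere_silhouette_points(focus, head_world, stem.head_radius,
                                             cfg.n_contour_points)
        taper3d = cone_silhouette_segments(focus, cone_world, stem.taper_s_range)

        def noisy(points3d, sigma):
            img = _project_view(scene, idx, np.atleast_2d(points3d))
            return img + rng.normal(0.0, sigma, img.shape) if sigma > 0 else img

        fid_obs = box.fiducial_markers[:, :2].copy()
        if cfg.noise_sigma_cal > 0:
            fid_obs = fid_obs + rng.normal(0.0, cfg.noise_sigma_cal, fid_obs.shape)
        ctl_obs = noisy(box.control_markers, cfg.noise_sigma_cal)
        views.append(ViewObservations(
            fiducials=fid_obs,
            controls=ctl_obs,
            bone_markers=noisy(bone_world, cfg.noise_sigma_2d),
            implant_markers=noisy(implant_world, cfg.noise_sigma_2d),
            head_contour=noisy(contour3d, cfg.noise_sigma_2d),
            taper_silhouette=noisy(taper3d.reshape(-1, 3),
                                   cfg.noise_sigma_2d).reshape(2, 2, 2),
            stem_tip=noisy(tip_world, cfg.noise_sigma_2d)[0],
            shaft_upper=noisy(shaft_upper_world, cfg.noise_sigma_2d)[0],
        ))
    meta = {
        "schema": EXAM_SCHEMA,
        "patient_id": patient.patient_id,
        "visit_months": visit.months,
        "side": cfg.side,
        "group": patient.group,
        "head_radius": stem.head_radius,
    }
    return Exam(views=views, meta=meta)


def generate_study(config: PhantomConfig) -> PhantomStudy:
    """Generate the full synthetic study (exams + ground truth) in memory.

    Deterministic per (config, seed): patients draw from independent spawned
    RNG streams so the output is reproducible even if generation order changes.
    """
    scene = config.scene()
    box = config.box()
    box.validate()
    schedule = np.asarray(config.schedule_months, dtype=float)
    mig_frac = trajectory_fractions(schedule, config.migration_pattern)
    slip_steps = default_slip_trajectory(config.total_slip, config.slip_pattern,
                                         schedule)
    groups = _group_assignment(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    width = max(2, len(str(config.n_patients)))
    patients: list[PatientTruth] = []
    exams: dict[str, dict[float, Exam]] = {}
    total_t = np.asarray(config.total_migration_translation, dtype=float)
    total_r = np.asarray(config.total_migration_rotation, dtype=float)
    for i, (group, ss) in enumerate(zip(groups, streams)):
        rng = np.random.default_rng(ss)
        pid = f"P{i + 1:0{width}d}"
        var = inject_patient_variation(config, rng, group)
        stem: StemTruth = var["stem"]
        taper_frame = build_taper_frame(stem.cone, stem.implant_markers,
                                        side=config.side)
        visits = []
        for j, months in enumerate(schedule):
            frac = mig_frac[j] * var["amp_migration"]
            migration = RigidTransform.from_euler_translation(
                *(frac * total_r), translation=frac * total_t)
            visits.append(VisitTruth(
                months=float(months),
                migration=migration,
                slip=slip_steps[j] * var["amp_slip"],
                pose=_visit_pose(config, rng, is_reference=(j == 0)),
            ))
        patient = PatientTruth(
            patient_id=pid, group=group, stem=stem,
            bone_markers=var["bone_markers"], taper_frame=taper_frame,
            amp_migration=var["amp_migration"], amp_slip=var["amp_slip"],
            visits=visits,
        )
        patients.append(patient)
        exams[pid] = {v.months: _make_exam(config, scene, box, patient, v, rng)
                      for v in visits}
    return PhantomStudy(config=config, scene=scene, box=box,
                        patients=patients, exams=exams)


def _truth_to_dict(patient: PatientTruth) -> dict:
    stem = patient.stem
    return {
        "schema": TRUTH_SCHEMA,
        "patient_id": patient.patient_id,
        "group": patient.group,
        "amp_migration": patient.amp_migration,
        "amp_slip": patient.amp_slip,
        "bone_markers": patient.bone_markers.tolist(),
        "stem": {
            "implant_markers": stem.implant_markers.tolist(),
            "shaft_point": stem.shaft_point.tolist(),
            "shaft_direction": stem.shaft_direction.tolist(),
            "tip": stem.tip.tolist(),
            "cone": {"axis_point": stem.cone.axis_point.tolist(),
                     "axis_direction": stem.cone.axis_direction.tolist(),
                     "half_angle": stem.cone.half_angle},
            "taper_s_range": list(stem.taper_s_range),
            "head_center": stem.head_center.tolist(),
            "head_radius": stem.head_radius,
        },
        "taper_frame": patient.taper_frame.matrix.tolist(),
        "visits": [
            {"months": v.months,
             "migration": transform_to_dict(v.migration),
             "slip": v.slip.tolist(),
             "pose": transform_to_dict(v.pose)}
            for v in patient.visits
        ],
    }


def write_study(study: PhantomStudy, out_dir: Path | str) -> Path:
    """Write a study to disk: manifest, box/scene models, per-patient exams and
    ground truth. Byte-identical for identical (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = study.config.model_dump(mode="json")
    save_json({
        "schema_versions": {"exam": EXAM_SCHEMA, "truth": TRUTH_SCHEMA},
        "config": cfg_dict,
        "config_hash": config_hash(cfg_dict),
        "seed": study.config.seed,
        "n_patients": study.config.n_patients,
    }, out / "manifest.json")
    save_json(box_to_dict(study.box), out / "box.json")
    save_json(scene_to_dict(study.scene), out / "scene.json")
    for patient in study.patients:
        pdir = out / "patients" / patient.patient_id
        save_json(_truth_to_dict(patient), pdir / "truth.json")
        for months, exam in study.exams[patient.patient_id].items():
            save_exam(exam, pdir / f"exam_{visit_token(months)}.json")
    return out
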