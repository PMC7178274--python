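"""Per-patient longitudinal migration analysis.

Ties the measurement chain together: view calibration, triangulation of
markers and landmarks, EGS sphere/cone fits, virtual-marker construction,
implant-to-bone migration by marker-based and EGS routes (with reference-point
correction), head-taper migration in the reference taper frame, quality
gating against the standard RSA thresholds, and cohort summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConvergenceError, InputError
from .egs import (
    TaperFrame,
    VirtualMarkerSet,
    ConeModel,
    build_taper_frame,
    construct_virtual_markers,
    fit_cone_axis,
    fit_sphere_center,
    vector_in_frame,
)
from .geometry import CalibrationBoxModel, ViewCalibration, calibrate_view, \
    reconstruct_point
from .io import Exam
from .kinematics import (
    MigrationSixDoF,
    RigidBodyQuality,
    RigidTransform,
    condition_number,
    correct_reference_point,
    euler_angles,
    fit_rigid_body,
    migration_of_point,
)

__all__ = [
    "QualityThresholds",
    "DEFAULT_THRESHOLDS",
    "ExamAnalysis",
    "PatientSeries",
    "MigrationRecord",
    "HeadTaperMigration",
    "DescriptiveStats",
    "analyze_exam",
    "quality_gate",
    "implant_to_bone_migration",
    "head_taper_migration",
    "descriptive_stats",
    "cohort_summary",
    "migration_table",
    "headtaper_table",
    "series_from_study",
    "series_from_dir",
]

METHODS = ("marker", "egs", "egs_corrected")


@dataclass(frozen=True)
class QualityThresholds:
    """Standard RSA quality gates; comparisons are inclusive (<=)."""

    max_calibration_error: float = 0.05  # mm
    max_focus_error: float = 0.5         # mm
    max_condition_number: float = 100.0
    max_rigid_body_error: float = 0.35   # mm

    def __post_init__(self):
        if min(self.max_calibration_error, self.max_focus_error,
               self.max_condition_number, self.max_rigid_body_error) <= 0:
            raise InputError("thresholds must be positive")


DEFAULT_THRESHOLDS = QualityThresholds()

GATE_KEYS = ("calibration_error", "focus_error", "condition_number",
             "rigid_body_error")


def quality_gate(metrics: Mapping[str, float],
                 thresholds: QualityThresholds = DEFAULT_THRESHOLDS
                 ) -> dict[str, bool]:
    """Pass/fail per criterion (True = passes). Inclusive boundaries."""
    limits = {
        "calibration_error": thresholds.max_calibration_error,
        "focus_error": thresholds.max_focus_error,
        "condition_number": thresholds.max_condition_number,
        "rigid_body_error": thresholds.max_rigid_body_error,
    }
    out = {}
    for key, limit in limits.items():
        if key not in metrics:
            raise InputError(f"metric {key!r} missing from quality metrics")
        out[key] = bool(metrics[key] <= limit)
    return out


@dataclass
class ExamAnalysis:
    """Everything the pipeline derives from one exam's raw observations."""

    calibrations: list[ViewCalibration]
    bone_points: np.ndarray       # (B, 3)
    implant_points: np.ndarray    # (3, 3)
    stem_tip: np.ndarray          # (3,)
    shaft_upper: np.ndarray       # (3,)
    head_center: np.ndarray       # (3,)
    head_fit_rms: float
    cone: ConeModel
    virtual: VirtualMarkerSet
    taper_frame: TaperFrame
    max_crossing_distance: float

    @property
    def calibration_error(self) -> float:
        return max(c.calibration_error for c in self.calibrations)

    @property
    def focus_error(self) -> float:
        return max(c.focus_error for c in self.calibrations)


def _triangulate(cals, img1, img2) -> tuple[np.ndarray, float]:
    rec = reconstruct_point(cals[0], cals[1], img1, img2)
    return rec.position, rec.crossing_distance


def analyze_exam(exam: Exam, box: CalibrationBoxModel,
                 side: str | None = None,
                 head_radius: float | None = None) -> ExamAnalysis:
    """Calibrate both views and reconstruct all 3D quantities of one exam."""
    side = side or exam.meta.get("side", "right")
    radius = head_radius if head_radius is not None else exam.meta["head_radius"]
    cals = [calibrate_view(box, v.fiducials, v.controls) for v in exam.views]
    v1, v2 = exam.views
    crossings: list[float] = []

    def tri(img1, img2):
        pos, cd = _triangulate(cals, img1, img2)
        crossings.append(cd)
        return pos

    bone = np.array([tri(a, b) for a, b in zip(v1.bone_markers, v2.bone_markers)])
    implant = np.array([tri(a, b)
                        for a, b in zip(v1.implant_markers, v2.implant_markers)])
    tip = tri(v1.stem_tip, v2.stem_tip)
    shaft_upper = tri(v1.shaft_upper, v2.shaft_upper)
    head_center, head_rms = fit_sphere_center(
        cals, [v1.head_contour, v2.head_contour], radius)
    cone = fit_cone_axis(cals, [v1.taper_silhouette, v2.taper_silhouette])
    virtual = construct_virtual_markers(head_center, axis_point=tip,
                                        axis_direction=shaft_upper - tip,
                                        stem_tip=tip)
    frame = build_taper_frame(cone, implant, side=side)
    return ExamAnalysis(
        calibrations=cals, bone_points=bone, implant_points=implant,
        stem_tip=tip, shaft_upper=shaft_upper, head_center=head_center,
        head_fit_rms=head_rms, cone=cone, virtual=virtual, taper_frame=frame,
        max_crossing_distance=float(np.max(crossings)) if crossings else 0.0,
    )


@dataclass
class PatientSeries:
    """Ordered follow-up exams of one patient, visit 0 is the reference."""

    patient_id: str
    box: CalibrationBoxModel
    exams: dict[float, Exam]
    head_neck_length: str | None = None
    side: str = "right"
    _analyses: dict[float, ExamAnalysis] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if 0.0 not in self.exams:
            raise InputError("visit 0 (reference exam) is required")
        months = sorted(self.exams)
        if months[0] != 0.0:
            raise InputError("visit months must start at 0")
        self.exams = {m: self.exams[m] for m in months}

    @property
    def visits(self) -> list[float]:
        return list(self.exams)

    def analysis(self, months: float) -> ExamAnalysis:
        if months not in self.exams:
            raise InputError(f"no exam at {months} months for {self.patient_id}")
        if months not in self._analyses:
            self._analyses[months] = analyze_exam(self.exams[months], self.box,
                                                  side=self.side)
        return self._analyses[months]


@dataclass
class MigrationRecord:
    patient_id: str
    visit_months: float
    method: str
    migration: MigrationSixDoF | None
    quality: RigidBodyQuality
    pass_flags: dict[str, bool]
    gated_out: bool = False
    reasons: list[str] = field(default_factory=list)
    transform: RigidTransform | None = None


@dataclass
class HeadTaperMigration:
    """Head-taper slip at one visit, expressed in the reference taper frame
    (x medial-lateral ⟂ taper, y along the taper axis, z anterior-posterior)."""

    visit_months: float
    dx: float
    dy: float
    dz: float
    frame_id: str = ""
    valid: bool = True
    reason: str = ""

    def __post_init__(self):
        if self.valid and not np.all(np.isfinite([self.dx, self.dy, self.dz])):
            raise InputError("slip components must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])


def _stem_body(analysis: ExamAnalysis, method: str
               ) -> tuple[np.ndarray, np.ndarray]:
    """(points, reference point) of the stem rigid body for a method."""
    if method == "marker":
        pts = analysis.implant_points
        return pts, pts.mean(axis=0)
    pts = analysis.virtual.as_array()
    return pts, analysis.virtual.reference_point


def implant_to_bone_migration(series: PatientSeries, visit: float, method: str,
                              thresholds: QualityThresholds = DEFAULT_THRESHOLDS,
                              gate: bool = True) -> MigrationRecord:
    """Implant-to-bone migration between the reference exam and a follow-up.

    marker: rigid fit on the three tantalum stem markers, reference point =
    their centroid. egs: rigid fit on the virtual markers (head center, tip,
    axis projection), reference point = their centroid. egs_corrected: the egs
    transform with translations re-expressed at the marker centroid via the
    reference-point correction.
    """
    if method not in METHODS:
        raise InputError(f"unknown method {method!r}")
    ref = series.analysis(0.0)
    fu = series.analysis(visit)
    bone_T, _bone_rbe = fit_rigid_body(ref.bone_points, fu.bone_points)
    fit_method = "marker" if method == "marker" else "egs"
    ref_pts, ref_point = _stem_body(ref, fit_method)
    fu_pts, _ = _stem_body(fu, fit_method)
    stem_T, rbe = fit_rigid_body(ref_pts, fu_pts)
    migration_T = stem_T.then(bone_T.inverse())
    cn = condition_number(ref_pts)
    metrics = {
        "calibration_error": max(ref.calibration_error, fu.calibration_error),
        "focus_error": max(ref.focus_error, fu.focus_error),
        "condition_number": cn,
        "rigid_body_error": rbe,
    }
    flags = quality_gate(metrics, thresholds)
    quality = RigidBodyQuality(condition_number=cn, rigid_body_error=rbe)
    record = MigrationRecord(patient_id=series.patient_id, visit_months=visit,
                             method=method, migration=None, quality=quality,
                             pass_flags=flags, transform=migration_T)
    if not all(flags.values()):
        reasons = [f"{k} = {metrics[k]:.4g} exceeds threshold"
                   for k, ok in flags.items() if not ok]
        if gate:
            record.gated_out = True
            record.reasons = reasons
            return record
        warnings.warn(
            f"{series.patient_id} visit {visit} {method}: quality gates failed "
            f"({'; '.join(reasons)}) but gating is disabled", RuntimeWarning)
        record.reasons = reasons
    if method == "egs_corrected":
        d_egs = migration_of_point(migration_T, ref_point)
        marker_centroid = ref.implant_points.mean(axis=0)
        d = correct_reference_point(migration_T, d_egs, ref_point,
                                    marker_centroid)
        ref_point = marker_centroid
    else:
        d = migration_of_point(migration_T, ref_point)
    ang = euler_angles(migration_T)
    record.migration = MigrationSixDoF(tx=float(d[0]), ty=float(d[1]),
                                       tz=float(d[2]), rx=ang.rx, ry=ang.ry,
                                       rz=ang.rz, reference_point=ref_point)
    return record


def head_taper_migration(series: PatientSeries, visit: float
                         ) -> HeadTaperMigration:
    """Head-taper slip between reference and follow-up, in the reference taper
    frame: with T the stem-marker rigid transform (ref -> visit), the slip is
    T⁻¹(head_visit) - head_ref. The reference visit is exactly zero."""
    frame_id = f"{series.patient_id}-ref-taper"
    if visit == 0.0:
        return HeadTaperMigration(visit_months=0.0, dx=0.0, dy=0.0, dz=0.0,
                                  frame_id=frame_id)
    try:
        ref = series.analysis(0.0)
        fu = series.analysis(visit)
    except ConvergenceError as exc:
        return HeadTaperMigration(visit_months=visit, dx=float("nan"),
                                  dy=float("nan"), dz=float("nan"),
                                  frame_id=frame_id, valid=False,
                                  reason=str(exc))
    T, _ = fit_rigid_body(ref.implant_points, fu.implant_points)
    slip_global = T.inverse().apply(fu.head_center) - ref.head_center
    d = vector_in_frame(ref.taper_frame, slip_global)
    return HeadTaperMigration(visit_months=visit, dx=float(d[0]),
                              dy=float(d[1]), dz=float(d[2]),
                              frame_id=frame_id)


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    sd_population: float  # divisor n
    sd_sample: float      # divisor n-1; NaN when n == 1
    n: int


def descriptive_stats(values: Iterable[float]) -> DescriptiveStats:
    """Mean plus both standard-deviation conventions (population and sample)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise InputError("descriptive_stats requires at least one value")
    mean = float(np.mean(arr))
    sd_pop = float(np.std(arr, ddof=0))
    sd_sample = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return DescriptiveStats(mean=mean, sd_population=sd_pop,
                            sd_sample=sd_sample, n=int(arr.size))


def migration_table(series_list: Sequence[PatientSeries],
                    methods: Sequence[str] = METHODS,
                    thresholds: QualityThresholds = DEFAULT_THRESHOLDS,
                    gate: bool = True) -> pd.DataFrame:
    """Tidy migration table over a cohort (one row per patient/visit/method)."""
    rows = []
    for series in series_list:
        for visit in series.visits:
            if visit == 0.0:
                continue
            for method in methods:
                rec = implant_to_bone_migration(series, visit, method,
                                                thresholds=thresholds, gate=gate)
                row = {
                    "patient_id": rec.patient_id,
                    "visit_months": rec.visit_months,
                    "method": rec.method,
                    "tx": np.nan, "ty": np.nan, "tz": np.nan,
                    "rx": np.nan, "ry": np.nan, "rz": np.nan,
                    "cn": rec.quality.condition_number,
                    "rbe": rec.quality.rigid_body_error,
                    "gated_out": rec.gated_out,
                    "gate_reasons": "; ".join(rec.reasons),
                }
                for key, ok in rec.pass_flags.items():
                    row[f"pass_{key}"] = ok
                if rec.migration is not None:
                    m = rec.migration
                    row.update(tx=m.tx, ty=m.ty, tz=m.tz,
                               rx=m.rx, ry=m.ry, rz=m.rz)
                rows.append(row)
    return pd.DataFrame(rows)


def headtaper_table(series_list: Sequence[PatientSeries]) -> pd.DataFrame:
    """Tidy head-taper migration table (taper-frame mm), incl. visit 0 rows."""
    rows = []
    for series in series_list:
        for visit in series.visits:
            ht = head_taper_migration(series, visit)
            rows.append({
                "patient_id": series.patient_id,
                "visit_months": ht.visit_months,
                "dx": ht.dx, "dy": ht.dy, "dz": ht.dz,
                "frame_id": ht.frame_id,
                "group": series.head_neck_length,
                "valid": ht.valid,
                "flags": ht.reason,
            })
    return pd.DataFrame(rows)


def cohort_summary(data, group_by: str | None = None) -> dict:
    """Per-visit mean ± SD of each head-taper component plus migration rate.

    `data` is either a headtaper table (DataFrame) or a list of PatientSeries.
    Rate definition (declared): norm of the cohort-mean (dx, dy, dz) at the
    final visit divided by follow-up years; per-axis rates also returned.
    """
    if not isinstance(data, pd.DataFrame):
        data = headtaper_table(data)
    if group_by not in (None, "head_neck_length", "group"):
        raise InputError("group_by must be None or 'head_neck_length'")
    df = data[data["valid"]].copy()
    if df.empty:
        raise InputError("no valid head-taper records to summarize")
    keys = ["visit_months"] if group_by is None else ["group", "visit_months"]
    if group_by is not None and df["group"].isna().all():
        warnings.warn("grouping requested but no group labels present; "
                      "falling back to ungrouped summary", RuntimeWarning)
        keys = ["visit_months"]
    agg = df.groupby(keys)[["dx", "dy", "dz"]].agg(["mean", "std", "count"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    final = df[df["visit_months"] == df["visit_months"].max()]
    years = df["visit_months"].max() / 12.0
    mean_vec = final[["dx", "dy", "dz"]].mean().to_numpy()
    rate = float(np.linalg.norm(mean_vec) / years) if years > 0 else 0.0
    per_axis = {ax: float(abs(m) / years) if years > 0 else 0.0
                for ax, m in zip(("dx", "dy", "dz"), mean_vec)}
    out = {"per_visit": agg.reset_index(), "rate_mm_per_year": rate,
           "rate_per_axis_mm_per_year": per_axis}
    if group_by is not None and "group" in keys:
        out["group_counts"] = (df.drop_duplicates("patient_id")["group"]
                               .value_counts().to_dict())
    return out


def series_from_study(study) -> list[PatientSeries]:
    """Build PatientSeries from an in-memory PhantomStudy."""
    out = []
    for patient in study.patients:
        exams = study.exams[patient.patient_id]
        out.append(PatientSeries(patient_id=patient.patient_id, box=study.box,
                                 exams=dict(exams),
                                 head_neck_length=patient.group,
                                 side=study.config.side))
    return out


def series_from_dir(run_dir) -> list[PatientSeries]:
    """Build PatientSeries from a study directory written by write_study."""
    from .io import load_study_dir

    _manifest, box, _scene, exams = load_study_dir(run_dir)
    out = []
    for pid, per_visit in exams.items():
        meta = per_visit[min(per_visit)].meta
        out.append(PatientSeries(patient_id=pid, box=box, exams=per_visit,
                                 head_neck_length=meta.get("group"),
                                 side=meta.get("side", "right")))
    return out
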