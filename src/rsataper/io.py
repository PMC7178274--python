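"""Exam/ground-truth JSON formats and study-directory layout.

All 2D coordinates are millimetres in the (possibly re-digitized) film frame;
the per-view affine film mapping recovered during calibration absorbs any
in-plane re-digitization. Exam and truth schemas are versioned so runs are
auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from ._exceptions import InputError
from .geometry import CalibrationBoxModel, SceneGeometry
from .kinematics import RigidTransform

EXAM_SCHEMA = "rsataper-exam-1"
TRUTH_SCHEMA = "rsataper-truth-1"

__all__ = [
    "ViewObservations",
    "Exam",
    "exam_to_dict",
    "exam_from_dict",
    "save_exam",
    "load_exam",
    "save_json",
    "load_json",
    "box_to_dict",
    "box_from_dict",
    "scene_to_dict",
    "scene_from_dict",
    "transform_to_dict",
    "transform_from_dict",
    "load_study_dir",
    "visit_token",
]


def _arr(a) -> np.ndarray:
    return np.asarray(a, dtype=float)


@dataclass
class ViewObservations:
    """Digitized 2D observations of one X-ray view (mm, film frame)."""

    fiducials: np.ndarray         # (F, 2) calibration-box fiducials (film plane)
    controls: np.ndarray          # (C, 2) projected control markers
    bone_markers: np.ndarray      # (B, 2)
    implant_markers: np.ndarray   # (3, 2) tantalum stem markers
    head_contour: np.ndarray      # (K, 2) ball-head silhouette points
    taper_silhouette: np.ndarray  # (2, 2, 2) two line segments, endpoint pairs
    stem_tip: np.ndarray          # (2,) lowest point of the stem tip
    shaft_upper: np.ndarray       # (2,) proximal point of the shaft midline

    def __post_init__(self):
        for name in ("fiducials", "controls", "bone_markers", "implant_markers",
                     "head_contour", "taper_silhouette", "stem_tip",
                     "shaft_upper"):
            setattr(self, name, _arr(getattr(self, name)))


@dataclass
class Exam:
    """All observations of one patient visit: two views plus metadata."""

    views: list[ViewObservations]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.views) != 2:
            raise InputError("an exam carries exactly two views")


def _view_to_dict(v: ViewObservations) -> dict:
    return {
        "fiducials": v.fiducials.tolist(),
        "controls": v.controls.tolist(),
        "markers": {"bone": v.bone_markers.tolist(),
                    "implant": v.implant_markers.tolist()},
        "head_contour": v.head_contour.tolist(),
        "taper_silhouette": v.taper_silhouette.tolist(),
        "stem_tip": v.stem_tip.tolist(),
        "shaft_upper": v.shaft_upper.tolist(),
    }


def _view_from_dict(d: dict) -> ViewObservations:
    return ViewObservations(
        fiducials=d["fiducials"], controls=d["controls"],
        bone_markers=d["markers"]["bone"], implant_markers=d["markers"]["implant"],
        head_contour=d["head_contour"], taper_silhouette=d["taper_silhouette"],
        stem_tip=d["stem_tip"], shaft_upper=d["shaft_upper"],
    )


def exam_to_dict(exam: Exam) -> dict:
    meta = dict(exam.meta)
    meta.setdefault("schema", EXAM_SCHEMA)
    return {"views": [_view_to_dict(v) for v in exam.views], "meta": meta}


def exam_from_dict(d: dict) -> Exam:
    return Exam(views=[_view_from_dict(v) for v in d["views"]],
                meta=dict(d.get("meta", {})))


def save_json(obj: dict, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_json(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_exam(exam: Exam, path: Path | str) -> None:
    save_json(exam_to_dict(exam), path)


def load_exam(path: Path | str) -> Exam:
    return exam_from_dict(load_json(path))


def box_to_dict(box: CalibrationBoxModel) -> dict:
    return {"fiducial_markers": box.fiducial_markers.tolist(),
            "control_markers": box.control_markers.tolist(),
            "control_height": box.control_height}


def box_from_dict(d: dict) -> CalibrationBoxModel:
    return CalibrationBoxModel(fiducial_markers=d["fiducial_markers"],
                               control_markers=d["control_markers"],
                               control_height=d["control_height"])


def scene_to_dict(scene: SceneGeometry) -> dict:
    return {"foci": scene.foci.tolist(),
            "beam_intersection_angle": scene.beam_intersection_angle,
            "film_focus_distance": scene.film_focus_distance,
            "box_center": scene.box_center.tolist()}


def scene_from_dict(d: dict) -> SceneGeometry:
    return SceneGeometry(foci=d["foci"],
                         beam_intersection_angle=d["beam_intersection_angle"],
                         film_focus_distance=d["film_focus_distance"],
                         box_center=d["box_center"])


def transform_to_dict(t: RigidTransform) -> dict:
    return {"rotation": t.rotation.tolist(), "translation": t.translation.tolist()}


def transform_from_dict(d: dict) -> RigidTransform:
    return RigidTransform(rotation=d["rotation"], translation=d["translation"])


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def visit_token(months: float) -> str:
    """Stable filename token for a visit, e.g. 1.5 -> 'm1.5', 12 -> 'm12'."""
    return f"m{months:g}"


def load_study_dir(run_dir: Path | str):
    """Load a generated study directory.

    Returns (manifest, box, scene, exams) where exams is a nested dict
    patient_id -> {months: Exam}.
    """
    run_dir = Path(run_dir)
    manifest = load_json(run_dir / "manifest.json")
    box = box_from_dict(load_json(run_dir / "box.json"))
    scene = scene_from_dict(load_json(run_dir / "scene.json"))
    exams: dict[str, dict[float, Exam]] = {}
    for pdir in sorted((run_dir / "patients").iterdir()):
        if not pdir.is_dir():
            continue
        per_visit: dict[float, Exam] = {}
        for f in sorted(pdir.glob("exam_*.json")):
            exam = load_exam(f)
            per_visit[float(exam.meta["visit_months"])] = exam
        exams[pdir.name] = per_visit
    return manifest, box, scene, exams
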