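# rsataper

Radiostereometric analysis (RSA) of implant migration, focused on the
head–taper junction of total hip stems. The package implements the full
measurement chain as reusable, tested components:

- **`rsataper.geometry`** — uniplanar stereo X-ray geometry: central
  projection onto a film plane, two-plane calibration-box calibration of each
  view (affine film mapping + focus recovery with quality numbers), and 3D
  triangulation of stereo correspondences.
- **`rsataper.kinematics`** — rigid-body migration kinematics: SVD point
  registration, condition number (100/σ₂ of the centered marker
  configuration), rigid-body error, z·y·x Euler decomposition, migration of a
  reference point, and reference-point correction
  `d(new) = d(old) + (R − I)(new − old)`.
- **`rsataper.egs`** — elementary-geometrical-shape pose recovery: sphere
  center from silhouette contours (known radius, tangent-ray least squares),
  cone/taper axis from silhouette lines (tangent-plane constraints),
  virtual-marker construction (head center, stem tip, axis projection), and
  the taper coordinate frame (Y along the taper axis, X medial in the
  implant-marker plane, Z = X × Y).
- **`rsataper.pipeline`** — per-patient longitudinal analysis:
  implant-to-bone migration by marker-based, EGS and reference-point-corrected
  EGS routes; head–taper migration expressed in the reference exam's taper
  frame; quality gating at the standard RSA thresholds
  (calibration ≤ 0.05 mm, focus ≤ 0.5 mm, CN ≤ 100, RBE ≤ 0.35 mm, inclusive);
  descriptive statistics and cohort summaries.
- **`rsataper.comparison`** — method interchangeability statistics:
  Bland–Altman with LoA = mean ± 1.96·SD against the RSA accuracy thresholds
  (0.5 mm / 1.15°), one-sample t-tests on intermethod differences, Pearson
  correlation of differences vs head–taper migration with Fisher-Z inference.
- **`rsataper.phantom`** — synthetic phantom generator: deterministic,
  ground-truth-paired studies with a two-focus 40°/140 cm setup, a 3×3+3×3
  two-plane calibration box, a stem with three tantalum markers, taper cone
  (half-angle 2.8055°) and 28 mm ball head, bone markers, the standard
  follow-up schedule (0, 1.5, 3, 6, 12, 24, 60, 120 months), three-phase
  migration/slip trajectories, patient repositioning, per-patient variation
  and Gaussian 2D digitizing noise.

## CLI

```sh
rsataper simulate  --config cfg.yaml --seed 1 --out run/   # phantom study
rsataper calibrate --study run/ --out results/             # view calibrations
rsataper migrate   --study run/ --out results/             # migration.csv
rsataper headtaper --study run/ --out results/             # headtaper.csv
rsataper compare   --study run/ --out results/ --group     # comparison.csv
rsataper report    --study run/ --out results/ --plots     # cohort summary
```

The config YAML accepts any `rsataper.phantom.PhantomConfig` field, e.g.

```yaml
n_patients: 20
noise_sigma_2d: 0.05
total_slip: [0.0, -0.115, 0.0]
slip_pattern: three_phase
```

Study directories contain a manifest (config hash, seed, schema versions),
the box/scene models, and per-patient exam + ground-truth JSON files. All
formats are plain text.

## Conventions

Global frame = calibration-box frame: +x medial, +y cranial, +z anterior for
a right hip (left hips mirrored at ingest); film plane z = 0, foci at
z = +1400 mm. All lengths mm, angles degrees. Head–taper slip is expressed in
the *reference* exam's taper frame, which removes stem rotation from the slip
vector. The cohort migration rate is ‖mean (dx, dy, dz) at the final visit‖
divided by follow-up years; per-axis rates are also emitted.
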