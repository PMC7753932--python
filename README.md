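# hip3d

Radiation-free 3D analysis of the hip joint for hip-preservation
research: fully automatic two-stage segmentation of MRI-like volumes,
3D morphometry of the segmented joint, method-agreement statistics, and
periacetabular-osteotomy (PAO) simulation — all validated end-to-end on
a synthetic hip phantom with analytic ground truth.

## The problem

Assessing femoroacetabular impingement (FAI) and developmental
dysplasia of the hip (DDH) in young adults requires 3D models of the
femur and acetabulum.  CT delivers them easily but irradiates young
patients; MRI avoids radiation but makes manual segmentation slow.  The
pipeline implemented here automates the MRI route and measures whether
the automatic 3D models support the same diagnostic parameters and
surgical (PAO) planning as manually derived models:

1. **Landmark stage** — a fully convolutional encoder–decoder regresses
   a volume-wise heatmap whose peak is the femoral head center (FHC).
2. **Segmentation stage** — the joint region cropped around the FHC is
   segmented into femur / acetabulum / background by an **LP-U-Net**: a
   3D U-Net with a space-to-depth (holistic decomposition) input stage
   and a depth-to-space (dense upsampling) output stage,

   `x → space_to_depth(k) → U-Net → conv to classes·k³ → depth_to_space(k) → scores`.

3. **Morphometry** — from the 3D models: acetabular inclination and
   anteversion, the lateral center-edge angle (LCE), the extrusion
   index, and total/anterior/posterior femoral head coverage; rule-based
   deformity labels (cam α > 60°, pincer LCE > 40°, DDH LCE < 22°, …).
4. **Statistics** — Dice / precision / recall / average surface distance
   / Hausdorff against reference labels; Pearson r, paired differences,
   Bland–Altman limits of agreement and ICC(2,1) between measurement
   methods.
5. **PAO simulation** — rigid reorientation of the acetabular fragment
   about the FHC with before/after morphometry.

Clinical images are not distributable, so the package ships a phantom
generator (`hip3d.phantom`) producing MRI-like hip volumes whose labels,
FHC and all seven diagnostic parameters are known analytically — e.g. a
hemispherical cup covers exactly 50 % of the head, a 60° cup 25 %.
Every stage is tested against these closed forms; see `docs/methods.md`
for models, conventions and limitations.  The two networks are NumPy
implementations sized for a single CPU and are exposed as
scikit-learn-style estimators (`LandmarkLocator`, `HipSegmenter`).

## Worked example

Generate one default phantom (hemispherical cup, inclination 54°,
anteversion 17°, 0.8 mm voxels) and measure it:

```sh
$ hip3d phantom --out ph --n 1 --seed 7
wrote 1 phantom(s) to ph
$ hip3d morph --labels ph/s0_labels.nii.gz --json report.json
wrote report.json
```

`report.json` (abridged):

```json
{
  "inclination_deg": 53.99,
  "anteversion_deg": 17.00,
  "lce_deg": 42.92,
  "extrusion_index_pct": 14.10,
  "total_cov_pct": 50.06,
  "anterior_cov_pct": 40.69,
  "posterior_cov_pct": 59.42,
  "head_radius_mm": 23.995
}
```

Reading: the cup orientation is recovered to within ~0.01° of the
generative 54°/17°; the hemispherical cup covers 50.06 % of the head
(analytic value 50 %); with 17° anteversion the posterior hemisphere is
better covered (59.4 %) than the anterior (40.7 %); the head radius
(24 mm) is recovered to 5 µm.  An LCE of 43° with extrusion index 14 %
describes a deeply covered hip — `classify_deformity` would call
LCE > 40° pincer-type overcoverage.

The full study design — phantom cohort, patient-grouped 3-fold
cross-validation of both networks, accuracy metrics, morphometry
agreement between ground-truth-derived and automatically-derived
models, PAO demo — runs as one command:

```sh
hip3d crossval --out run/ --n 24 --folds 3 --seed 7
```

writing `crossval_metrics.csv`, `fhc_detection.csv`,
`agreement_table.csv`, `morphometry_per_hip.csv` and `pao_demo.json`.

## Layout

| module | contents |
| --- | --- |
| `hip3d.phantom` | synthetic hip generator + analytic ground truth |
| `hip3d.io_formats` | NIfTI volumes/labels, PLY/STL meshes, CSV/JSON tables |
| `hip3d.landmark` | heatmap targets, `LandmarkLocator`, ROI cropping |
| `hip3d.segmentation` | space-to-depth ops, LP-U-Net, `HipSegmenter`, grouped k-fold CV |
| `hip3d.evaluation` | Dice/precision/recall, surface extraction, ASD/Hausdorff, ICP |
| `hip3d.morphometry` | head-sphere fit, rim, cup angles, coverage, LCE/EI, deformity rules |
| `hip3d.agreement` | Pearson, paired differences, Bland–Altman, ICC(2,1) |
| `hip3d.pao` | fragment selection, rigid reorientation, before/after reports |
| `hip3d.pipeline` / `hip3d.cli` | end-to-end runner and `hip3d` command |
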