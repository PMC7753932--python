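# Methods

`hip3d` implements a radiation-free analysis chain for the hip joint:
fully automatic two-stage segmentation of MRI-like volumes, 3D
morphometry of the segmented joint, accuracy and method-agreement
statistics, and a periacetabular-osteotomy (PAO) simulation.  Because
no clinical images ship with the package, every component is validated
against a synthetic hip phantom whose morphometry is known in closed
form.  This note records the models, conventions, parameter choices and
their limits.

## Anatomical frame and cup-orientation convention

All geometry lives in one fixed frame: **+x lateral, +y anterior,
+z superior**, with world coordinates `origin + index * spacing` (mm).
The acetabular opening axis — the outward normal of the opening plane —
is constructed from the two clinical angles as

    n = ( sin i · cos a,  sin a,  −cos i · cos a ),

so inclination `i = atan2(n_x, −n_z)` is the coronal tilt of the
opening from inferior toward lateral and anteversion `a = asin(n_y)`
the elevation toward anterior.  A cup with `i = a = 0` opens straight
inferiorly.  This single construction is shared by the phantom
generator and the morphometry module, so angle round-trips are exact by
design.  Which of the clinical anteversion conventions (radiographic,
anatomic, operative) external planning tools use cannot be recovered
from published summary tables; the convention above is simply the
package's documented one.

## The hip phantom

The phantom emulates a T1 VIBE-like acquisition (0.8 mm isotropic by
default) of one hip:

* **femur** — head sphere (default radius 24 mm) plus neck cylinder
  (radius 11 mm, length 30 mm, default axis = the cup opening axis, i.e.
  pointing out of the joint); bright marrow interior with a dark
  cortical shell (1.5 mm);
* **acetabulum** — a spherical shell concentric with the head, inner
  radius = head radius + joint space (3 mm), thickness 5 mm, restricted
  to a cap of configurable half-angle about the opening axis, with an
  optional azimuthal "rim deficiency" sector removed (sector azimuth 0 =
  anterior); marrow interior with cortical linings;
* **image** — piecewise-constant intensities (soft tissue 40, marrow
  100, cortical 15), multiplied by a low-order random polynomial bias
  field (amplitude = maximal relative deviation) and corrupted by
  additive Gaussian noise.

Labels are rasterized by voxel-center membership and never depend on
noise or bias.  The default cup angles (inclination 54°, anteversion
17°) sit at the means reported for symptomatic young-adult cohorts, and
the cohort generator draws inclination 44–63°, anteversion 7–30°, cup
half-angle 65–95° and head radius 20–26 mm uniformly, with ±4 mm head
jitter and ~20 % bilateral hips (both hips of a patient then share a
patient id).  Analytic ground truth: total coverage is the exact cap
fraction `(1 − cos θ)/2 · (1 − deficiency/360°)`; anterior/posterior
coverage are integrated over a 100 000-direction Fibonacci lattice with
the exact membership test; LCE and extrusion index are evaluated on the
analytic rim circle with the same projection formulas as the
measurement code.

What the phantom does **not** model: MRI physics (k-space, chemical
shift, arthrographic contrast), cartilage/labrum, aspherical (cam)
heads, subluxation, or osseous texture.  Tests passing on phantoms
therefore demonstrate the correctness of the geometry, learning and
statistics machinery under controlled conditions — not clinical-grade
segmentation accuracy.

Of note, the cup is *concentric* with the femoral head by construction.
One geometric consequence: rotating the acetabulum about the femoral
head center (the PAO model below) maps the covered direction set onto a
rotated copy of itself, so **total coverage is exactly invariant under
the simulated PAO**, even though LCE, extrusion index and the
anterior/posterior split change as expected.  In real dysplastic hips
coverage increases after PAO because the joint is not concentric; a
non-concentric phantom would be needed to reproduce that effect.

## Two-stage segmentation

**Stage 1 — landmark detection.** A fully convolutional encoder–decoder
(3-level U-Net, 8 base channels) regresses a volume-wise heatmap whose
peak marks the femoral head center (FHC).  The input volume is
average-pooled by a working factor (default 2) and intensity-scaled;
the target is a world-space Gaussian `exp(−‖x − fhc‖²/2σ²)` (σ = 6 mm
default — at least one working voxel) scaled by an amplitude factor
(default 20).  The amplitude matters: with a unit-peak target the MSE
of so sparse a map has a strong all-zero local optimum and small
desk-scale runs collapse into it; scaling the target restores a usable
gradient signal while leaving detection (argmax + 3³ intensity-weighted
centroid, mapped back to world coordinates) scale-invariant.  Because
the collapse is initialization-dependent, `fit` additionally compares
the final training loss against the best-constant-predictor MSE (the
collapse plateau, computed from the training targets) and
deterministically reinitializes on failure (up to 3 restarts, recorded
in `n_restarts_`); the segmenter applies an analogous relative-decrease
guard on runs of at least 10 epochs.  Loss is mean squared error
(standard for heatmap regression); optimizer Adam (lr 1e-3, 8 epochs by
default).

**Stage 2 — LP-U-Net segmentation.** A 48³-voxel region of interest is
cropped around the detected FHC (zero-padded at the borders, with an
offset record for lossless placement of results back into the original
frame).  The network is a 3D U-Net whose input passes through a
space-to-depth rearrangement ("holistic decomposition", factor k = 2:
k³ channels at 1/k resolution) and whose head emits `classes·k³`
channels reassembled to full resolution by depth-to-space ("dense
upsampling").  Both rearrangements are exact bijections and inverses of
each other.  Depth 3, 8 base channels, softmax over 3 classes
(background / femur / acetabulum), argmax prediction with
lowest-class-index tie-break.  Loss is cross-entropy plus soft Dice
with configurable weights (defaults 1/1); the Dice term averages over
the *foreground* classes only, since background overlap is already
driven by cross-entropy and would otherwise dominate the average.
Adam, lr 1e-3, 40 epochs by default.

The networks are implemented in NumPy (im2col convolutions with
analytic backprop, verified against numeric differentiation), sized for
a single CPU.  Both are exposed as scikit-learn-style estimators
(`LandmarkLocator`, `HipSegmenter`) with `fit`/`predict`,
`get_params`/`set_params` and trailing-underscore fitted attributes.

**Study design.** Cross-validation is patient-grouped: whole patients
are randomly assigned to k = 3 folds (greedy size balancing), so hips
of one patient never straddle the train/test boundary; the fold plan
validates this invariant and the partition property.  The desk-scale
study conditions are 24 hips at 1.6 mm isotropic resolution in a 64³
field of view, additive noise at 5 % of the marrow intensity and a 5 %
bias field.  At these conditions the pipeline reaches held-out Dice
around 0.96 (femur) and 0.91 (acetabulum) with mean FHC detection
errors near 2 mm — deliberately a scaled-down analog of, not a
substitute for, training full-resolution networks on clinical MRI.

## Evaluation metrics

Overlap metrics are voxel-set arithmetic per structure (one-vs-rest):
Dice `2|P∩R|/(|P|+|R|)` (both-empty convention: 1.0 — agreement on
absence), precision `|P∩R|/|P|`, recall `|P∩R|/|R|` (empty denominators
are errors, flagged per structure).  Surface metrics are mesh-based,
matching a surface-model comparison workflow: iso-surfaces at level 0.5
of the (optionally Gaussian-presmoothed) binary mask via marching cubes
with spacing-aware coordinates; distances are exact point-to-triangle
projections (Ericson's region method, vectorized; a KD-tree over
triangle centroids restricts candidates on large meshes, with an
exhaustive path below 512 faces that doubles as the oracle route in
tests).  ASD is symmetric — the mean of the two directed vertex-to-
surface means — and the Hausdorff distance is the maximum over both
directions; whether published ASD values are one-directional is usually
unstated, so the symmetric choice is documented here.  A
distance-transform fallback (`surface_distances_edt`) is provided for
speed and cross-checked against the mesh route.

Rigid alignment (`icp_align`) is point-to-plane ICP: closest-point-on-
surface correspondences, linearized normal-distance minimization per
iteration, centroid pre-alignment, monotone RMS with tolerance-based
stopping.  Point-to-plane was chosen after point-to-point stalled a few
degrees short on the sphere-dominated femur; with exact-copy targets it
recovers 15°/10 mm perturbations to machine precision.

## Morphometry

From a label map (or meshes directly) the pipeline computes:

1. **Head sphere / FHC** — RANSAC over femur vertices within 1.5× the
   expected radius (24 mm) of the initial center (landmark output or
   label centroid): 200 four-point algebraic sphere hypotheses, 0.5 mm
   inlier tolerance, radius-plausibility gate, algebraic refinement on
   inliers; < 30 % inlier support raises "no spherical head found";
   radii outside 15–35 mm are flagged.
2. **Articular patch** — largest connected acetabular component with
   `| ‖v−c‖ − r |` within joint space (3 mm) + tolerance (2 mm; kept
   tight so the patch hugs the lunate surface rather than the rim
   band while still absorbing surface-extraction error).
3. **Rim** — the longest open boundary loop of the patch, snapped
   radially to the patch's median articular radius; opening plane by
   least squares, normal oriented out of the cup; cup angles from the
   normal by the frame convention above.
4. **Coverage** — 10 000 Fibonacci directions from the FHC; a direction
   is covered iff its ray hits the acetabular surface within 1.5× the
   head radius (Möller–Trumbore over KD-tree-prefiltered candidate
   triangles).  Anterior/posterior coverage are covered fractions
   *within* each hemisphere (split at the coronal plane through the
   FHC), so a symmetric cup has anterior = posterior = total.
5. **LCE / extrusion index** — coronal (xz) projections at the most
   lateral rim point: LCE = angle at the FHC between superior and the
   ray to that point (positive lateral); EI = `max(0, (c_x + r) −
   x_rim) / 2r · 100`.
6. **Deformity rules** — cam iff α > 60°, pincer iff LCE > 40°, mixed
   iff both, DDH iff LCE < 22°, increased/decreased femoral version
   > 25° / < 10° (α and femoral version are supplied externally; their
   measurement needs radial reformats and the distal femur, outside
   this package's inputs).

Round-trip accuracy on noise-free phantoms: angles within ~0.1° for
intact rims, coverage within ~0.2 pp, head radius within ~0.01 mm;
with a rim-deficiency sector the *plane* of the remaining rim loop
genuinely tilts, so recovered "anteversion" deviates from the generative
cup axis — a property of the geometry, not an estimation error, and the
reason angle round-trip tests use intact rims.

## Agreement statistics

For paired measurement series (two methods, same hips): Pearson r with
the t-transform p-value; signed and absolute paired differences
(mean ± SD and ranges); Bland–Altman bias with 1.96·SD limits of
agreement (classical multiplier, no small-sample t correction); and
ICC(2,1) — two-way random effects, absolute agreement, single
measurement — from the ANOVA decomposition with the F-based 95 % CI
(verified against `pingouin`'s ICC table).  Absolute agreement is the
conservative choice for method comparison; negative ICC point estimates
are clamped to zero with a flag, and degenerate (zero-variance) inputs
return ICC 1 with a degenerate-CI flag.  A normality pre-check is
deliberately not a branching criterion.

## PAO simulation

The acetabular fragment is selected by a sphere cut around the FHC
(single-parameter stand-in for the surgical osteotomy planes; the
partition fragment/remainder is exact and the fragment must contain the
articular patch), rotated rigidly about the FHC by extrinsic x-y-z
angles (rotations above 60° are flagged as outside the planning range,
not fatal), and the full morphometry is recomputed on the reoriented
joint.  The rotation is an exact isometry about the pivot (vertex
distances preserved to 1e-9 mm).  A 15° lateral tilt of a 60° dysplastic
cup raises LCE by ~14.5° and lowers the extrusion index accordingly;
total coverage stays constant for the concentric phantom (see above).

## Numerical and design choices

* float32 for images and network tensors; float64 for geometry.
* Argmax tie-breaks take the lowest class index; RANSAC and ICP seeds
  are fixed and exposed; every stochastic stage takes an explicit seed
  and the end-to-end runner derives per-stage seeds from one master
  seed, making rerun CSVs byte-identical.
* Iso-surface smoothing default 0.6 voxels in the pipeline: enough for
  sub-voxel surface placement on smooth anatomy, small enough not to
  erode the 5 mm cup shell.
* Problem sizes in the test-suite and acceptance script (24 hips, 64³ at
  1.6 mm, 8/40 training epochs, 10 000 coverage rays) are the package's
  desk-scale study conditions: small enough to run on one CPU core,
  large enough that every contract is exercised end-to-end.

## Known limitations

* Phantom contrast is schematic; no claim about VIBE appearance.
* No GPU path; the NumPy networks are desk-scale by design and do not
  reproduce clinical-cohort Dice values (the tables those came from
  require the original patient MRI, which is not distributable).
* Coverage under simulated PAO is invariant (concentric phantom); see
  the phantom section.
* `LPUNet` requires the dense-upsampling factor to equal the
  decomposition factor so output resolution matches input resolution.
* DICOM ingestion, non-rigid registration and biomechanics are out of
  scope.
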