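# Methods

## Geometric model

The diagnostic-to-simulation transition is modelled as a continuous
per-point transformation `T_θ(p) = p + Δ_sys(p) + Δ_pat(p)`: a
deterministic, protocol-dependent offset (couch curvature, missing
immobilization) plus a patient-specific residual. The two terms are never
separated at inference — both networks predict their sum — but the package
exposes a cohort-mean vs residual decomposition for analysis of generator
output. The training objective is mean-squared displacement error plus a
smoothness term `λ·‖∇T_θ‖²`. Since predictions exist only on discrete
axial slices, the gradient penalty is realized as the mean squared finite
difference of predicted displacements between z-adjacent slices *within a
patient* (only within-patient adjacency is anatomically meaningful); this
finite-difference realization is a documented design choice.

### Coordinates and conventions

All physical coordinates are millimetres in LPS (+x left, +y posterior,
+z superior); voxel arrays are `[slice, row, col]`, slices
inferior→superior. Polar body contours use θ = 0° → +x, θ = 90° → +y
(posterior), θ = 180° → −x, so [0°, 180°] covers the couch-contact surface.
The anterior half-plane is never modified by the body correction: the
observable gap is at the body bottom, and freezing the anterior contour
avoids inventing unconstrained deformation.

### Spine correction

The heart-contour centroid is the anatomical anchor: it is stable relative
to the thoracic vertebrae and segmentable on both scans. Per slice, the
heart→cord vectors `V` (dCT) and `V′` (sCT) give the regression target
`ΔV = V′ − V`. Trajectories from scanners with different slice spacing are
matched by linearly interpolating the dCT centroids onto the sCT z-grid
restricted to the overlapping range. At application time each axial slice
is translated **rigidly in-plane** by its predicted displacement (the
per-slice map is a translation of the spinal position; local deformation
within a slice is unconstrained by the data), with the z-component applied
first as a 1-D resampling of slice positions. Although the displacement is
predicted in 3-D, slice-matched construction makes the z-component vanish
identically whenever both trajectories are sampled on a common grid; the
z-resampling path exists and is tested for externally supplied fields.
Displacements beyond the cord-bearing range are clamped to the nearest
defined slice. A physical-plausibility bound (default 50 mm per slice)
rejects degenerate fields.

### Body-bottom correction

Per slice, the body surface is parameterized as offsets from the
(corrected) spine centre at uniformly sampled angles, default 1° steps
(181 angles) for sub-voxel angular resolution on millimetre grids; the
phantom pipeline uses 3° steps (61 angles), which is sub-voxel at its 2 mm
in-plane spacing. Rays take the **outermost** body crossing so re-entrant
geometry (arms) still yields the dose-relevant external surface. The warp
stretches tissue piecewise-linearly along each ray between the spine centre
(fixed point) and the boundary, so the source boundary lands exactly on the
target boundary; voxels outside the new boundary become air (−1000 HU).
The voxel row straddling the spine-centre line is included in the remap so
the θ ≈ 0°/180° rays are corrected too; content strictly anterior is
untouched.

Interpolation: linear for HU, nearest-neighbour for masks, ties at exact
0.5 resolved toward the lower index. Identity inputs reproduce the volume
to ≤ 1 HU.

## Networks and training

Both regressors are 64-128-64 ReLU MLPs trained with Adam
(lr 10⁻³, weight decay 10⁻⁵), one optimization step per patient
(batch = all slices of one patient, ordered by z) so intra-patient
correlation dominates slice noise. Inputs and outputs are standardized
per-feature over the training set; constant output features fall back to a
tiny (10⁻⁶) scale so constant targets are reproduced exactly and
predictions are invariant to affine unit rescaling. Weights use uniform
fan-in initialization from the config seed; training is bit-reproducible
given (data, seed). Defaults: 2000-epoch budget with early stop after a
200-epoch plateau (relative improvement < 10⁻⁵); λ = 0.01 on normalized
outputs. λ was never reported numerically for this class of model, so 0.01
is a deliberately gentle default: on smooth displacement fields it barely
changes predictions, and its smoothing effect only becomes reliably
measurable around λ ≈ 0.1 (where the regularizer test operates). The
trainer is plain numpy — the networks are far too small to justify a GPU
framework — and checkpoints are JSON (spec, weights, normalization stats).

The body network consumes the full flattened offset vector (2 × n_angles
inputs) per slice rather than regressing angle-by-angle: the contour moves
as a coherent surface, and the whole-contour mapping lets the network use
cross-angle shape context.

## Synthetic phantom

The generator emulates exactly the geometry gap the method corrects, on a
96×96×60 grid at (2, 2, 3) mm (desk-scale minutes):

* analytic solids — elliptical body (flattened posteriorly at the couch
  plane), cylindrical cord (r = 4 mm), canal (r = 8 mm) and vertebral body
  (r = 14 mm, 300 HU ≈ trabecular bone), ellipsoidal heart and lungs,
  cylindrical PTV (r = 18 mm over the central 60 mm) — rasterized so ground
  truth is exact;
* couch sag `A·exp(−x²/2w²)` with A = 12 mm, w = 60 mm (Gaussian-in-x,
  constant-in-z trough);
* spine offset `Δ_sys(z)` (per-axis polynomial; defaults give per-patient
  median in-plane offsets of ≈ 4–11 mm, median ≈ 6.5 mm across a cohort,
  matching the magnitude reported for unimmobilized diagnostic positioning)
  plus a smooth patient residual (5-knot cubic spline, sd σ_pat = 1 mm,
  detrended per patient so the systematic part stays identifiable from
  cohort means);
* ±15% body-size scatter across patients; prescription 30 Gy (palliative
  30 Gy/10 convention).

Not emulated: HU texture, metal artifacts, contrast, respiratory motion,
weight change between scans, and cord-independent organ motion — so
passing tests demonstrate that the machinery recovers learnable systematic
geometry, not that clinical soft-tissue alignment is solved.

## Toy dose engine

Parallel-beam, primary-only exponential attenuation with
μ = μ_w·(HU+1000)/1000 (μ_w = 0.02 /mm), default two opposed AP/PA beams
(3D-CRT palliative geometry). Plans are normalized to PTV mean =
prescription; recalculation on another geometry reuses beams and factor
without renormalization (monitor-unit transfer), isolating the geometric
dose effect. No scatter, buildup, or beam model: absolute DVH shapes are
not clinical, only *differences between geometries under a fixed plan* are
meaningful. One consequence: under mean normalization the PTV dose spread
keeps V100 near 50% even on the reference sCT, so the strict V100 ≥ 95% /
V107 ≤ 5% conformity set fails on every geometry; the default plan-level
goal set is therefore a palliative-style one (D95 ≥ 75% Rx, V100 ≥ 40%,
Dmax ≤ 140% Rx, ±2% tolerance) that the reference plan satisfies, making
the pass-rate comparison discriminative. Both sets are reported by the
reproduction script.

## Evaluation conventions

* D95/D99: lower-interpolated order statistic (largest dose received by at
  least 95%/99% of voxels) — the conservative discrete convention, since
  planning systems disagree.
* V100/V107: thresholds relative to prescription, not Dmax.
* DVH curves: 0 to 1.15·Rx in 0.5%-of-Rx steps; RMS DVH difference is the
  pointwise root-mean-square on that axis. Dose-endpoint errors are
  reported as % of prescription and volume endpoints as percentage points.
* Dice of two empty masks ≡ 1.0 (identity of indiscernibles). HD95 is the
  max of the two directed 95th-percentile surface distances; surfaces are
  boundary voxels.
* Wilcoxon signed-rank: zeros dropped (Pratt's variant available), ties
  mid-ranked, exact enumeration of all 2^m sign assignments for m ≤ 12,
  tie-corrected normal approximation with continuity correction above;
  two-sided by default.
* Gwet's AC2: quadratic weights `w_kl = 1 − (k−l)²/16` on the 5-point
  scale; chance term from overall category propensities. Band labels:
  ≤ 0.20 slight, ≤ 0.40 fair, ≤ 0.60 moderate, ≤ 0.80 substantial, above
  that almost perfect (upper edges inclusive).
* No multiple-testing correction across DVH endpoints (per-metric p-values
  are reported as such).

## Problem sizes

The reproduction script and the end-to-end tests use a 40-train / 8-test
cohort at the default generator conditions, 800/400 epoch budgets for the
spine/body networks, and 61 contour angles — sizes chosen so a full study
runs in minutes on one CPU while leaving the learning problem
non-trivial. Unit tests use a 64×64×24 grid variant of the same phantom.

## Known limitations

* The spine warp is rigid per slice; genuinely local deformation around
  the cord is outside the model.
* The body warp assumes star-convexity of the posterior body about the
  spine centre on each slice; pathological geometries fall back to the
  outermost-crossing rule.
* The dose engine is a geometric-sensitivity instrument only.
* DICOM support is import-only (CT series + RT-STRUCT rasterization);
  NIfTI is the canonical format. An optional bone-threshold centroid
  alignment is a convenience, not a registration algorithm.
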