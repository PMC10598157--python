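# Methods

## Model and procedure

The package treats a segmented CT volume as a rigid assembly of point
masses located at voxel centers.  A voxel's mass is its calibrated density
times the voxel volume (`kg/m³ × mm³ × 1e−9 = kg`); all internal arithmetic
is SI, and results are reported in the field's customary units (g, cm³, mm,
kg·cm²).  The chain for one subject is:

1. **Calibration.**  Six rods of known density (air → cortical bone) give
   (mean HU, density) pairs; two OLS lines are fitted, split at the muscle
   rod's mean HU, with the muscle rod in both segments so six rods
   determine both lines.  Evaluation uses `HU ≤ breakpoint → lower segment`
   to stay single-valued, and clamps predicted density at zero (the lower
   segment extrapolated to air can undershoot).  Because the two segments
   are fitted independently they need not meet at the breakpoint; the
   mapping is then monotone within each segment but may step at the
   breakpoint (the bundled synthetic rod table yields a ≈15 kg/m³ drop).
   The inverse map (density → HU), used only for phantom voxelization,
   requires strictly positive slopes and routes densities at or below the
   lower segment's breakpoint value through the lower inverse.
2. **Segmentation.**  Head: global −300 HU threshold (≥, inclusive), then
   the largest 26-connected component — a deterministic stand-in for manual
   removal of disconnected support material.  Brain: bone at ≥250 HU,
   optional morphological closing (ball radius in voxels, default 0) to
   seal foramina, 6-connected flood fill of non-bone from the volume
   border, and the largest enclosed non-bone region is the cranial cavity;
   brain voxels are its sub-250 HU members.  Foreground 26 / background 6
   connectivity prevents cavity leakage through diagonal voxel contacts.
3. **Cutting planes.**  Planes through three landmarks (head–neck: LNT,
   LOC, ROC; ears: tragus / intertragal notch / anterior notch, each side).
   A voxel is kept iff its center's signed distance is ≥ 0; on-plane voxels
   are retained.  The head–neck plane keeps the side holding the head-mask
   centroid; ear planes keep the side holding the ACS origin.  The
   head–neck plane is applied to head and brain masks first, then the ear
   planes to the head mask; since each application is a set intersection,
   the ear-plane order is immaterial.
4. **ACS.**  Origin at the RZ–LZ midpoint; x toward the RF–LF midpoint;
   preliminary y toward RZ; z = x × y_prelim; final y = z × x.  The final
   cross product is taken in this operand order so the frame stays
   right-handed with y still pointing toward the right-lateral side.  The
   rotation is stored with rows as axes, making world→ACS a plain
   rotate-then-translate.
5. **Inertia.**  Tensor about the ACS origin from the point-mass sums with
   the negative-integral product convention; parallel-axis translation to
   the CoM in full tensor form `I_CoM = I_ACS − M(|d|²E − ddᵀ)` (the
   scalar `Σ mᵢd²` form generalized component-wise, validated against
   direct recomputation about the CoM); eigenvalues sorted ascending to
   match the published table order, eigenvector signs fixed by positive dot
   product with the same-rank ACS axis (first nonzero component positive on
   ties).
6. **Air rule.**  Voxels below −500 HU inside a segment (air pockets in
   ex vivo brains) are assigned the mean density of the segment's non-air
   voxels; they stay in the mask and count toward volume.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| head threshold | −300 | HU | separates soft tissue from air |
| bone threshold | 250 | HU | bone mask enveloping the brain |
| air threshold | −500 | HU | intracranial air reassignment |
| closing radius | 0 | voxels | phantoms have closed shells; real skulls need > 0 |
| on-plane tie-break | keep | — | documented fixed choice |
| SD denominator | n − 1 | — | sample SD, consistent with the published Mean/SD rows |

## Synthetic phantom

The phantom emulates the *composition* of a pre-adolescent pig head — a
soft-tissue ellipsoid (semi-axes 70 × 62 × 95 mm, 1040 kg/m³, ≈1.84 kg)
containing an ellipsoidal bone shell (36 × 32 × 34 mm outer, 6 mm wall,
1700 kg/m³) whose interior is a brain ellipsoid (30 × 26 × 28 mm,
1035 kg/m³, ≈95 g), plus a neck cylinder (r = 25 mm) that abuts the
soft-tissue ellipsoid at the head–neck plane — at the study's scale
(≈2.5 kg heads, ≈100 g brains).  ACS landmarks sit on the bone surface;
condyle/nuchal landmarks span the head–neck plane, tangent to the caudal
apex of the soft-tissue ellipsoid, so the cut removes exactly the neck;
ear-plane triplets lie on planes tangent to the widest lateral extent
(the phantom has no ears, so those cuts are exercised but remove nothing).
The whole assembly is rigidly rotated/translated into the scanner frame so
the ACS construction is non-trivial.

Densities are sampled at voxel centers (no partial-volume anti-aliasing)
and mapped to HU through the inverse calibration; optional Gaussian HU
noise is seeded.  Ground truth comes from closed-form solid formulas
composed by the parallel-axis theorem; overlapping primitives must resolve
to full containment (later primitives overwrite earlier ones), which keeps
the composition exact — partial overlap raises an error rather than
silently double-counting.  Containment detection is exact for co-oriented
ellipsoid chains and boxes and conservative otherwise.

What passing phantom tests do **not** show: robustness to real skull
morphology (foramina, sinuses, teeth), partial-volume blur at tissue
interfaces, beam hardening or scatter, endotracheal tubes, or landmark
palpation error.  Landmarks are exact by default; a jitter study would use
the landmark entries directly.

## Problem sizes and numerical choices

Phantom validation uses grids at 2, 1 and 0.5 mm (≈0.7 M → 42 M voxels);
0.5 mm matches the study's in-plane resolution scale and gives sub-0.01%
mass/MoI errors, with the aggregate error decreasing monotonically under
refinement.  The omitted per-voxel cube inertia is O(spacing²) and uniform.
Regression recovery uses residual noise calibrated by the variance
decomposition `r² = var(signal)/(var(signal) + σ²)` with body mass uniform
on 18–48 kg, 100 cohorts of n = 200 for the mean r², and 1000 cohorts of
n = 11 (the study's cohort size) for 95% CI coverage of the slope; p-values
use the t formulation (identical to F for simple regression).

Tensor symmetry is enforced by exact symmetrization after a 1e−9 relative
check; eigendecomposition uses the symmetric solver.  Reported table
rounding is 1 decimal (mm, g, cm³) and 2 decimals (kg·cm²).  Reproduction
of published summaries from the bundled tables is checked at ±0.1 (±0.3 mm
for quantities combining two tables), the slack implied by the printed
rounding of the inputs.

## Limitations

- No DICOM series assembly, registration, or HU resampling; volumes enter
  as NIfTI/NRRD with trustworthy affine metadata.
- The world frame is whatever the file stores; only FCSV import converts
  (RAS↔LPS sign flip) to the configured convention (default LPS).
- Manual segmentation correction and endotracheal-tube removal are out of
  scope; the largest-component and enclosed-cavity rules are their
  deterministic stand-ins.
- Cohort statistics assume a common ACS definition across subjects; no
  uncertainty propagation from landmark placement is performed.
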