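# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `pelvimetry3d`, in the spirit of a methods appendix.

## Coordinate conventions

All geometry lives in the scanner world frame defined by the NIfTI affine,
RAS+ orientation, millimeter units. Landmark files (Slicer-style `.fcsv`
and the package's JSON schema) use the same frame.

## Surface modeling

Each bone mask is padded with background voxels and iso-surfaced at 0.5
with marching cubes. The binary indicator is first smoothed with a
Gaussian of σ = 0.8 voxels: raw binary marching cubes produces a
staircase surface whose area overshoots the true surface by ~8% on a
10 mm sphere, while the smoothed version is accurate to well under 1%.
If smoothing would erase a very thin segment (maximum below the
iso-level) the raw mask is used instead. Watertightness is guaranteed by
the padding; outward orientation is enforced via the sign of the signed
volume.

Decimation is Garland–Heckbert quadric edge collapse with area-weighted
plane quadrics, a link-condition test that preserves 2-manifoldness, and
a triangle-flip guard. The loop stops at the exact vertex budget (default
25,000 per bone, giving 2V−4 ≈ 50,000 faces on genus-0 surfaces), which
makes the mesh resolution reproducible across inputs. Collapse targets
solve the 3×3 quadric system in closed form and fall back to the best of
midpoint/endpoints when the quadric is near-singular. The procedure is
deterministic for a fixed input and target.

The Dice index is computed on voxel grids; if two segmentations live on
different grids the second is resampled onto the first with
nearest-neighbor interpolation. The Hausdorff distance is the exact
symmetric maximum (100th percentile by default; the percentile is a
parameter for robust variants) of point-to-triangle distances, evaluated
at mesh vertices plus seeded area-weighted random surface samples
(default 10,000 per mesh). Point-to-triangle queries use an exact
vectorized closest-point routine with candidates proposed by a k-d tree
over mesh vertices; exact ties between faces resolve to the lowest face
index.

## Registration

Similarity alignment minimizes mean squared distance to the target by ICP
with Umeyama updates. Because plain ICP is prone to local minima under
large rotations, five deterministic initializations are tried (identity
plus the four proper principal-axis alignments of the two point clouds)
and the best short-run result is refined to convergence (relative
residual change < 1e-6 or 100 iterations).

Non-rigid refinement solves, per stiffness stage α,

    min_D  Σ_i [ (n_i · (v_i + d_i − c_i))² + w_t ‖v_i + d_i − c_i‖² ]
           + α Σ_{(i,j)∈E} ‖d_i − d_j‖²

where c_i is the closest point on the target surface, n_i the normal of
its face, and E the source mesh edges. The point-to-plane data term lets
vertices settle onto the target without being dragged tangentially by
biased closest-point correspondences; the small point-to-point anchor
(w_t = 0.05) stabilizes the solve. The sparse 3N×3N normal equations are
re-factorized as correspondences update (SuperLU). The stiffness schedule
defaults to 8 geometric stages from 10 to 0.5; the residual reported per
stage is monotonically non-increasing. The solver is deterministic.

Correspondence accuracy was characterized on phantoms with analytically
known deformations: on the feature-rich phantom bones the mean
correspondence error is ≈ 0.4 mm for 1 mm deformation amplitude and
≈ 2 mm at 5 mm amplitude. On featureless surfaces (spheres) tangential
drift is substantially larger; this is intrinsic to
displacement-Laplacian regularization, which prefers low-gradient
displacement fields that slide along low-curvature regions. The phantom
generator therefore produces ridged, bumpy bones on purpose — and this is
also why results on phantoms do not bound the behavior on anatomically
smooth regions of real bone.

Landmarks are embedded as (face index, barycentric weights, signed normal
offset). The offset preserves points slightly off the decimated surface
through embed/project round trips; snapping to the surface is a flag.
Projection onto a mesh with different topology than the host is refused.

## Atlas construction and automatic labeling

The reference model is an iterative mean shape: the first model
(centroid-normalized) seeds the template; each iteration registers the
template to every model (whole-pelvis similarity, then per-bone
non-rigid), maps the deformed template back into the template pose with a
rigid (no-scale) Procrustes fit so the reference keeps the average size of
the population, and averages corresponded vertices. Consensus landmarks of
each model are carried into the template parametrization by embedding them
barycentrically on the deformed template and evaluating the embedding on
the mapped-back mesh; their means are re-embedded on the averaged meshes
after the final iteration. Three mean iterations are the default; the
construction is deterministic given model order.

Automatic labeling registers the reference to the target the same way and
projects every embedded landmark. A configurable mean-residual threshold
(default 2 mm) flags dubious registrations on the returned landmark set.

## Pelvimetry measures

The canonical roster has 12 landmarks: promontory and lower sacrum border
on the midline (sacrum), and ten bilateral landmarks on the hips (superior
and inferior pubic symphysis borders, pubic tubercle, iliopectineal
eminence, ischial spine, ischial tuberosity, inferior ischial ramus,
antero- and postero-superior iliac spines, iliac crest) — 22 instances in
a complete labeling. The 15 packaged measures (13 lengths, 2 angles:
subpubic as apex-and-rays, pectineal as the angle between the two
pectineal lines) are shipped as a versioned YAML config; measures are
declarative so alternative rosters or definitions are a config file, not
code. Angles are computed in 3D without projection to a plane; midline
measures touching bilateral structures use midpoints of the left/right
pair. All measures are rigid-motion invariant; lengths scale linearly and
angles are scale-invariant.

## Reliability statistics

Leave-one-out errors follow the evaluation design: each rater's landmark
(measure) is compared with the mean of the remaining raters' positions
(values); the automatic method is compared with the all-rater consensus.
ICC is the two-way mixed, consistency family: with BMS and EMS the
between-subject and residual mean squares of the two-way ANOVA,
ICC(3,1) = (BMS−EMS)/(BMS+(k−1)EMS) and ICC(3,k) = (BMS−EMS)/BMS.
Negative estimates are reported as computed and classified "poor"
(classification: excellent ≥ 0.9 > good ≥ 0.75 > moderate ≥ 0.5 > poor).
SEM = SD·√(1−ICC) with SD pooled over all observations of the measure; a
negative ICC is floored at zero inside the radical and flagged. The
Wilcoxon signed-rank test drops zero differences, uses mid-ranks for
ties, and computes the exact two-sided p by enumerating all 2ⁿ sign
vectors for up to 25 nonzero pairs (the exact path is valid under ties);
larger samples use the normal approximation with tie and continuity
corrections. D'Agostino's K² wraps the standard skewness/kurtosis omnibus
statistic and requires n ≥ 8. Manual-vs-automatic comparisons pair on
(subject, segmentation, item) with the manual value taken as the mean of
the raters' leave-one-out errors for that item; note this pairing is a
package convention, not uniquely determined by the evaluation design. No
multiple-testing correction is applied; p-values are reported raw.

## Synthetic phantoms

The phantom population stands in for the clinical study data
(10 CT scans × 3 segmentation operators × 3 raters), which is not
distributable. Design and defaults:

* **Template** — three closed, genus-0, radially parametrized shells
  (ellipsoid base plus angular harmonics creating ridges and bumps):
  a sacrum-like wedge on the midline and two mirror-image hip shells.
  All 22 landmarks are exact parametric surface points; bilateral
  instances mirror across x = 0 to machine precision. Default mesh
  resolution: icosphere subdivision 3 (642 vertices per bone) — small
  enough for fast registration, rich enough for the geometry.
* **Population variability** — a band-limited random displacement field
  (6 random spatial harmonics, wavelength 60 mm, well above the mesh edge
  length) scaled so the maximum vertex displacement equals the amplitude
  parameter (default 5 mm). Deformations that invert any triangle are
  resampled from a derived seed. The exact field is returned for oracle
  use.
* **Raters** — isotropic Gaussian noise with a per-landmark sd map
  (defaults 1.2–5 mm) mimicking the observed heterogeneity between
  easy landmarks (symphysis borders, ischial spine) and hard ones
  (iliac crest, inferior ramus). Real rater error is surface-constrained
  and biased toward salient features; isotropic noise is a simplification,
  so rater-noise results validate the statistics pipeline, not human
  behavior.
* **Voxel loop** — scan-line parity voxelization (a voxel center is
  inside iff an axis ray crosses the closed surface an odd number of
  times; columns carry tiny irrational offsets so degenerate hits cannot
  occur), default spacing 1.0×1.0×1.5 mm, within the CT resolutions the
  study design emulates. Repeat segmentations displace each segment
  boundary by a smooth Gaussian random field (sd 0.4 mm, correlation
  2 voxels) applied to a half-voxel-corrected signed distance transform;
  conflicts between segments resolve to the smallest perturbed signed
  distance.
* **Seeding** — one global seed fans out via `numpy.random.SeedSequence`
  spawning (subjects, then raters/operators per subject), so any
  sub-sample of the study is independently reproducible.

What the phantoms do *not* emulate: anatomical shape statistics (the
between-subject variability is a smooth 5 mm field, much smaller than real
inter-subject pelvic variation), CT intensity artifacts, or structured
rater bias. One visible consequence: with the default amplitudes some
measures have little between-subject variance relative to rater noise, so
inter-rater ICCs on the synthetic study span a wider (lower) range than
clinical reliability studies report. Passing tests therefore demonstrate
correctness of the algorithms and statistics under known ground truth,
not clinical performance levels.

## Problem sizes and defaults used in checks

The packaged checks run the atlas pipeline with 5 training and 10
held-out phantoms, two mean iterations, and the default bone resolution;
the mesh-budget check voxelizes one phantom hip at 0.8 mm spacing
(≈ 40k extracted vertices before decimation to 25,000). These sizes were
chosen as the smallest populations at which the recovery statistics are
stable across seeds.

## Known limitations

* Non-rigid correspondence degrades on low-curvature, feature-poor
  regions (tangential ambiguity); automatic landmarks inherit that error.
* The reference construction averages in the template's topology; it does
  not re-mesh, so a poor template triangulation propagates.
* ICC forms are the consistency family only; absolute-agreement forms are
  out of scope.
* The exact Wilcoxon path enumerates 2ⁿ sign vectors and is capped at
  n = 25 nonzero pairs by default.
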