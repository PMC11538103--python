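# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of `lsatrace`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and intensity conventions

Volumes are axis-aligned 3D grids with per-axis spacing in mm; physical
coordinates are `origin + index * spacing` with 0-based indices
(direction cosines beyond axis alignment are out of scope). Intensities
carry a `raw`/`standardized` tag. Standardization maps the robust window
[p0.5, p99.5] linearly onto [0, 255] and clips; the percentile guard keeps
hot voxels from compressing the window. The pre-screen thresholds
T_bg = 80 and T_v = 120 are defined on this standardized scale, which is
what makes them portable across inputs. Standardization is per-volume and
idempotent; a constant volume maps to the midpoint with a warning.

## Preprocessing

Order: bias correction → denoising → isotropic resampling →
standardization. Bias correction divides by a strictly positive smooth
multiplicative field — N4 via SimpleITK when selected (shrink-factor
sized to the grid, 3×30 iterations), or an in-package least-squares
polynomial fit (degree 3 by default) to log-intensities — and rescales so
the volume mean is preserved within 1%. Non-positive inputs are shifted
positive for the fit and shifted back. Denoising is a plain linear mean
filter (default 3³; median offered); learned denoisers are a non-goal.
Resampling is trilinear onto an isotropic grid (default 0.10 mm; sensible
range 0.10–0.20 mm); the output extent matches the input within one
target voxel, and targets below 0.01 mm are rejected as a memory guard.
Masks resample nearest-neighbor so they stay binary.

## Small-patch CNN

Segmentation is center-voxel detection: only voxels with standardized
intensity strictly inside (T_bg, T_v) are classified; voxels ≥ T_v are
large vessel by fiat and ≤ T_bg background, so the three sets partition
the grid. The classifier sees a normalized cube around the voxel
(normalization bounds are the min/max over the *training* patches, and the
same bounds must be reused at inference).

The architecture is three (conv k3, stride 2, pad 1 → batch-norm → ReLU)
blocks with one 2³ max-pool after the first block, feature maps held
constant (default 128) until the dense layers (dense width 256 → 1
sigmoid unit). The exact block count and dense widths are a design choice
of this package; a scaled-down configuration (9³ patches, 16 feature
maps, dense 32) is used for CPU-scale training and testing. The loss is
the summed binary cross-entropy, optimized with Adam (initial learning
rate 1e-4 at full scale; 3e-4 for the scaled configuration, whose loss
surface is much smaller), with a reduce-on-plateau schedule: ×0.1 after
10 non-improving test epochs, floored at 1e-8. Training defaults to 80
epochs with early stop at 40 and batch size 25. The whole network is
implemented in numpy with explicit forward/backward passes; the test
suite checks every layer's gradient against central differences and the
parameter count against a hand derivation.

Patch labels: a patch is positive iff its center voxel is ground-truth
vessel. Edge handling is replication. Untied design points: the
probability cutoff on the sigmoid output defaults to 0.5 (exposed); the
final mask merges the large-vessel set by default, with a
small-vessels-only flag.

## Synthetic phantoms (the study conditions)

Phantoms render tubes (linear-interpolated centerline polylines with
per-point radii) on the standardized scale directly: background 60, small
tubes 100, large vessel 200, so the printed thresholds are meaningful on
synthetic data. Ground-truth masks use the hard center-in rule (voxel
center within the interpolated radius — unambiguous for metric oracles);
rendered intensity is antialiased by 2× supersampling per axis. Additive
Gaussian noise (default SD 10 for generic phantoms; SD 15 wherever a
"noisy" condition is called for) and an optional positive polynomial bias
field complete the model. Branching trees draw branching angles uniformly
from 30–70° per seed, with child radii tapering by 0.75 per generation
within the 0.1–0.75 mm radius range of the target vessels. Everything is
seeded; identical spec + seed renders bit-identical volumes.

Training patch sampling: positives are mask voxels (with the local tube
direction recorded and binned over 18 hemisphere directions for coverage
checks — the generator places tubes spanning ≥ 18 distinct directions);
negatives are either pre-screen-interval voxels ("interval", the hard,
inference-relevant class) or flat background voxels ≥ 2 voxels from any
vessel ("background"). The phantom-mode training protocol mixes the two
negative classes half-and-half: interval negatives teach the vessel-wall
decision, background negatives anchor the flat-noise regime. The
separable evaluation sets use core positives (≥ 1 voxel inside the
surface) with background negatives; interval-selected negatives
adjacent to the vessel wall are genuinely ambiguous at the half-voxel
level, so accuracy on them is not a separability measure. A stride
parameter subsamples candidate centers (sampling density along vessels is
otherwise every voxel).

What the phantoms do **not** emulate: MR flow physics (saturation,
pulsation), partial-volume blur beyond supersampling, anisotropic noise,
skull/background anatomy, and contact between unrelated vessels. Passing
phantom tests therefore demonstrates the machinery — recovery of known
geometry under additive noise — not clinical segmentation accuracy.

## Tracking

Steps are cylinders of height 3 voxels. Candidate directions come from a
40-point Fibonacci sphere filtered to a 60° cone around the previous
axis (plus the previous axis itself); candidate radii span
{0.5, 0.75, 1, 1.25, 1.5}× the current radius, clipped to [0.5, 10]
voxels. Candidates with vessel fraction f1 < 0.2 or that claim no new
vessel voxel are pruned before scoring. The score is
`p_forest − 0.2·E` with energy
`E = −(mean centerline depth / radius) + 0.5·f3²`, a minimal-path-style
cost (depth = distance-transform values sampled along the candidate
axis); tracking stops when the best score falls below 0.3. Accepted
endpoints are recentered on the local mask cross-section slab, the
radius is refreshed from the distance transform, and the cylinder's
voxels are claimed as visited (termination follows from the finite,
monotone visited set). Two numerical clean-ups matter at the half-voxel
scale: interior track points are smoothed with a (¼, ½, ¼) kernel to damp
the zigzag of the discrete direction grid, and on STOP the tail is
trimmed while the inscribed radius at the last point is < 0.6× the branch
median — steps otherwise overrun into the rounded end cap.

The step forest is a scikit-learn random forest (default 2,000 trees)
with bootstrap resampling per tree providing the per-iteration sample
randomization; out-of-bag accuracy is reported. Feature vectors are
(f1, f2, f3, f4, λ1, λ2, λ3) with the Hessian eigenvalues computed from
Gaussian derivatives (σ = 1.5 voxels — σ is interpreted in voxels at the
working resolution) on 11³ neighborhoods of both cylinder endpoints in
the original image, averaged as matrices and sorted ascending. Training
examples are synthesized from phantom ground truth: on-axis cylinders
with jittered tangents (valid) versus off-vessel, strongly misaligned,
and past-the-end cylinders (invalid).

Bifurcation detection intersects a spherical shell (radius 2× local
radius, thickness 1.5 voxels) with the mask and counts 26-connected
components; the component best aligned with the backward direction is
the incoming vessel. Children leaving at narrow angles merge on a tight
shell, so the radius is scanned over {1, 1.33, 1.67, 2}× and the scale
resolving the most components wins; components under 3 voxels are
dropped and near-parallel directions (< 30°) merged, since a shell
grazing a tube surface fragments. Because the shell test can fire up to
one shell radius before the true junction, the junction is refined by
least-squares intersection of the stem line (from the recent track) and
the child centerline lines (estimated from shell-component centroids at
two radii); detections are deduplicated within the largest scanning
radius, and child directions are re-measured from the refined junction.
A branch ends when ≥ 2 children appear; each child is traced as a new
branch of order parent + 1 (orders above 3 are reported as 3).

Seeding: with a large-vessel mask, seeds sit where small-vessel
components touch its 1-voxel dilation, pointing away from the large
vessel. Without one (phantom mode — a documented deviation from
anatomical seeding at the internal carotid origins), each component is
seeded at a geodesic tip: BFS inside the mask finds the two geodesically
extremal ends, the seed snaps to the highest-inscribed-radius voxel near
a tip (preferring the wider tip — vessel stems are widest), and the
initial direction points inward. Geodesic BFS is used because a medial
skeleton is not required for endpoints and 3D thinning proved unreliable
in the deployed image-processing stack.

## Screening

Three rule-based filters, in order, then branch orders are recomputed:

- **Duplicates** (repeated tracking): branches are visited longest-first;
  a branch whose densified points lie ≥ 70% within 1 voxel of a kept
  branch is dropped, with a genuinely novel trailing tail (> 2 voxels)
  re-attached as a child of the branch it duplicated at the divergence
  point — this preserves true secondary branches discovered via a
  duplicated stem.
- **Artifacts** (pulsation near large vessels): branches ≥ 50% inside the
  artifact zone (large-vessel mask dilated by 1 mm) that are either
  tortuous (path/chord > 2) or poorly supported by the vessel mask
  (< 80% of points inside) are removed. An empty large-vessel mask makes
  this the identity.
- **Noise**: branches shorter than 2 mm or with < 80% mask support are
  removed; children re-parent to the nearest surviving ancestor.

All thresholds live in `ScreeningConfig` and serialize with results.
Screening never adds points and is idempotent; whether the reference
screening stage was rule-based or learned is not determinable from the
available description, and a rule-based model was chosen.

## Modeling and comparison

Centerlines are piecewise cubic Béziers built from Catmull-Rom-style
local tangents, so they interpolate every tracked point exactly with C¹
joints. Arc length uses polyline refinement doubling the sampling until
the relative change is < 1e-4; curvature is the analytic
|B′×B″|/|B′|³. Diameters are measured in the plane perpendicular to the
local tangent: the mask is resampled (nearest-neighbor) on a half-voxel
grid offset by half a cell (keeping sample points off voxel-boundary
planes, where round-to-even halves the measured area), the connected
in-plane region containing the centerline gives an area A, and
d = 2√(A/π); the profile is median-filtered with window 3, and
out-of-mask samples inherit the nearest valid diameter and are flagged.
The mask cross-section was chosen over intensity FWHM because tracking
operates on the mask.

Model comparison matches branches greedily by symmetric mean
closest-point distance (threshold 1 mm, exposed); key points are samples
at matched arc-length fractions every 0.5 mm plus endpoints (a
reproducible, dense definition of "key point"); length and diameter
differences are signed (a − b) per matched branch using per-branch mean
diameters; Pearson r is reported per quantity (NaN when degenerate) and
Bland–Altman limits are mean ± 1.96·SD with the sample SD (ddof = 1).
Tube meshes sweep parallel-transported rings along the centerline with
end-cap fans (watertight per branch) and carry the diameter as a
per-vertex scalar for color mapping; export is PLY via trimesh, and
centerline polylines are written as ASCII legacy VTK.

## Pipeline, seeding and problem sizes

All randomness flows from one pipeline seed through named substreams
(SHA-256 of `seed:name`, reduced below 2³¹) so stages stay independent;
identical config + seed reproduce byte-identical deterministic artifacts,
which the manifest (config hash, per-artifact SHA-256) makes checkable.

Desk-scale problem sizes, chosen as the package's standard test
conditions: training phantoms of 48³ voxels at 0.1 mm with noise SD 15;
1,000 training patches (500 positive / 500 negative) at 9³ with 16
feature maps and 25 epochs; evaluation trees of 72³ with one bifurcation
level; step forests of 100–200 trees on 500–800 examples for fixtures
(2,000 trees remains the full-scale default); screening fixtures over 20
seeds. The full-scale settings (25³ patches, 128 feature maps, 17,000
patches at an 8:2 split, 2,000 trees) are the configuration defaults.

## Known limitations

- FP/FN rate definitions follow the printed convention (FP over vessel
  voxels, FN over background voxels), which is swapped relative to common
  usage; `fp_fn_rates_conventional` provides the usual one.
- No direction-cosine handling; NIfTI volumes are treated axis-aligned.
- Tracking does not bridge unsegmented gaps (discontinuous flow signal);
  such regions end branches and are left to screening, not inpainting.
- The bifurcation shell parameters and the screening thresholds are
  package defaults, exposed in config rather than derived from data.
- Phantom realism limits are listed above; none of the phantom-based
  accuracies transfer to clinical data without retraining and validation.
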