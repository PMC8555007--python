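# Methods

This note documents the models, defaults and numerical choices behind
`peridce`, and what its synthetic validation does and does not demonstrate.

## Data model and conventions

A dynamic series is an array indexed `(t, z, y, x)` — time leading, then
slice, row, column — with voxel spacing `(dz, dy, dx)` in mm and a frame
duration in seconds (default 58.5 s, the acquisition protocol's dynamic
scan time; override per file via a JSON sidecar key
`frame_duration_seconds`, the 4th NIfTI zoom, or configuration). All index
ranges are 0-based and half-open. Intensities keep their on-disk dtype on
read; every computation promotes to float64. File round-trips are bit-exact
for integer data.

The ROI is a 2D rectangle replicated across all slices by default,
matching the workflow of drawing the box on the slice with the largest
tumour cross-section and stretching it through the stack; an explicit
`z_range` is supported and recommended so the masked cylinder stays inside
the breast (otherwise columns can exit through skin and air, which the
4-cluster refinement would then have to absorb).

## Segmentation

**Scalar k-means.** Clustering operates on voxel intensity only. Lloyd
iterations stop when the largest centroid shift drops below the tolerance
(default 1e-4) or after 100 iterations (a warning is logged on
non-convergence and the result returned). Initialisation is k-means++;
because a single 1D start can land in a local optimum, `n_init` (default
10) restarts are drawn deterministically from the seed and the lowest
within-cluster sum of squares wins. On ≤ 12 scalar values the result
matches exhaustive enumeration of contiguous two-partitions in the test
suite. Clusters are always relabelled so label 0 is darkest; empty clusters
re-seed at the farthest point.

**Tumour chain.** MIP of the last post-contrast volume → 2-means →
brighter cluster → removal of 2D components below `min_object_area_2d`
(default 25 px; the study never quantified its "small objects") → stencil
multiplication through every slice and time point → 4-means on the nonzero
voxels of the first post-contrast volume → retained clusters → largest 3D
component. Masked-out (zero) voxels are excluded from the second
clustering; whether the original workflow kept them as a background cluster
is unknowable from its description, and excluding them avoids an intensity
cluster pinned at zero. The default retention rule takes the single
brightest-centroid cluster; an explicit cluster list reproduces the
observer-intervention step of the manual workflow. Connectivity defaults:
26 in 3D, 8 in 2D (the common Fiji-style defaults); components tie-break to
the lexicographically smallest seed voxel. Morphology treats voxels as unit
cubes, ignoring the 0.96 × 0.96 × 1 mm anisotropy, as the voxel-based
original did.

**Reference tissues.** The pre-contrast healthy-breast crop is clustered
with k = 3 (air / adipose / fibroglandular+skin). Adipose is the
middle-intensity cluster, used without erosion. FGT takes the brightest
cluster followed by binary erosion (6-connected unit element,
`erosion_iterations` default 3) to strip the skin rind, which shares the
cluster; erosion from the outside removes a thin closed shell long before
it significantly erodes a compact interior blob. An empty post-erosion mask
is an error (e.g. a one-voxel-thick structure).

## Shells

Shell *i* = dilate^i(tumour) \ dilate^(i−1)(tumour), with a 6-connected
(face-adjacent) structuring element by default, 26-connected optionally.
This makes shell *i* exactly the voxels at chamfer (city-block /
chessboard) distance *i* from the tumour — asserted against
`scipy.ndimage.distance_transform_cdt` on random masks. Dilation runs in a
padded lattice so voxels falling outside the image are identified, dropped,
and counted in a per-shell clipping report rather than raising. Shells are
not intersected with any tissue mask: the peri-tumoural gradient of
interest extends into adipose tissue.

## Kinetics

Curves are arithmetic means of the unmodified intensities under each mask,
per frame; times are `t × frame_duration / 60` minutes. The concentration
transform divides the signal change by `r1 · T1_ref · S0_ref` with r1 =
3.43 mM⁻¹s⁻¹ and T1_ref stored internally in seconds (0.366 s;
configuration accepts milliseconds and converts), giving mmol/L. S0_ref is
the adipose pre-contrast mean of the same breast's healthy crop unless
supplied explicitly.

S_peak is the maximum of the *region-mean* curve over post-contrast frames,
not averaged voxelwise maxima — the parameters are properties of the
region-level curve. SER with S_last = S0 is reported as missing with a
flag, never as ±∞ or 0. AUC integrates the concentration curve by the
trapezoid rule from the pre-contrast point (where C = 0 by construction) to
the last frame; the integration rule is a package choice, as is including
the pre-contrast point.

## Statistics

Group comparison is the pooled-variance two-tailed Student's t-test
(df = n1 + n2 − 2), deliberately not Welch, computed from group summaries
so published mean ± SD tables are first-class inputs. Pearson's r uses the
usual t transform for p. Cronbach's α uses unbiased variances; negative α
is allowed. ICC is fixed to the two-way mixed, consistency, single-measures
form ICC(3,1) = (MS_rows − MS_error)/(MS_rows + (k−1) MS_error), with the
95 % interval from F = MS_rows/MS_error; the implementation is from the
ANOVA mean squares directly and is cross-checked against `pingouin` in the
tests. Threshold classification predicts high grade iff value > threshold —
ties go to the low-grade class — and all five percent metrics derive from
the integer confusion matrix. `confusion_from_rates` reconstructs that
matrix from printed sensitivity/specificity and group sizes by nearest-int
rounding, which is how the bundled cohort table's PPV/accuracy/NPV cells
are shown to be internally consistent. No multiple-testing correction is
applied anywhere, mirroring the exploratory design.

## Phantom generator

The phantom is a geometric stand-in, not an MR physics simulation: no
relaxation forward model, coil profile or k-space. The default subject is a
40 × 80 × 80 grid at 1 × 0.96 × 0.96 mm with 7 frames of 58.5 s — the
acquisition geometry at reduced matrix size, chosen so a full pipeline run
takes well under a second. Tissues: air (S0 = 2), skin (S0 = 200, mild
persistent enhancement), adipose (S0 = 100, flat), FGT (S0 = 220,
persistent), tumour (S0 = 150, E1 = 150 %, SER = 1.1, washout). Curves are
piecewise linear — S0 to S1 over the first interval, then linear to S_last
determined by SER — so every kinetic parameter of the generating curve is
available in closed form. Voxels within 4 morphological steps of the tumour
gain `0.5^d` of the tumour's enhancement at step distance d, reproducing an
outward-decaying peri-tumoural gradient. The tumour ellipsoid (semi-axes
6 × 7 × 7 voxels) respects the > 7 mm minimum-diameter inclusion rule of
the study design. Noise is additive Gaussian (sd 5, i.e. 5 % of the adipose
baseline) clipped at zero — region means over hundreds of voxels are
near-Gaussian regardless, and a Rician option exists; the clip introduces a
small positive bias only where signal ≈ 0 (air).

Masks partition the grid exactly and ellipsoids are rasterised by
centre-of-voxel inclusion, so "truth" is defined to the voxel. Two seeds
differ only in noise.

**What passing phantom tests shows — and what it does not.** The phantom
has no partial-volume voxels, no motion, no B1/bias field, no
non-mass-enhancement, and tissue classes are intensity-separable by
construction. Dice ≈ 1 and SER recovery within 0.005 on phantoms therefore
validate the *implementation* (the chain of operations, its determinism and
its parameter plumbing), not clinical segmentation accuracy. SER recovery
is additionally insensitive to modest over-/under-segmentation here because
every tumour and peri-tumoural voxel shares the tumour's temporal shape —
real lesions are heterogeneous.

The FGT-recovery test uses a 1-voxel skin and one erosion step:
rasterisation stair-steps make a 2-voxel ellipsoidal shell locally thicker
than 2 voxels, so thicker skins leave remnants at any erosion depth small
enough to preserve an FGT blob of testable size. The pipeline default stays
at 3 erosions, sized for ~1 mm slices and 2–3 mm skin at clinical FGT
volumes.

**Cohorts.** `generate_cohort` draws per-subject first-post-contrast tumour
concentrations from grade-specific normal distributions — defaults
2.47 ± 1.61 (low grade, n = 12) vs 4.15 ± 1.86 mmol/L (high grade, n = 44),
the published cohort's summaries — truncated below 0.2 mmol/L by redrawing,
and back-computes each subject's tumour E1 so its generating curve realises
the drawn value exactly. Cohort simulations (null calibration, power)
operate on these curve-level truths rather than rasterising 56 volumes per
replicate; a rasterised spot-check confirms spec → phantom → pipeline
consistency.

## Problem sizes and determinism

The test suite and acceptance script use: 10 phantom seeds for end-to-end
recovery, 10 000 replicates for t-test type-I calibration, 300 for p-value
uniformity (KS), and 200 for the d = 2 power check — sizes at which the
full run completes in seconds on one core while Monte-Carlo error stays
well inside the asserted bands. Every random draw flows from an explicit
seed; pipeline outputs are byte-reproducible given (input, seed).

## Known limitations

- Non-mass enhancement and multi-lesion cases are out of scope; the
  largest-component rule assumes one clearly demarcated mass.
- No motion correction or registration between dynamics is performed or
  compensated.
- Shells are voxel-metric, not mm-calibrated; with anisotropic voxels a
  "one-voxel" shell is thinner through-slice in mm than in-plane.
- The reference-tissue concentration is an approximation; it inherits any
  error in the literature T1 of adipose tissue and assumes the linear
  low-concentration regime.
- DICOM support is read-only and expects a single-series directory with
  temporal position or acquisition-number tags.
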