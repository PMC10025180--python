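# Methods

## Scope and model

The package measures the morphology of the intraarticular space of a
metacarpophalangeal joint from an isotropic 3D image volume. The
processing chain is fixed:

1. **Bone segmentation** — mineralized bone is thresholded from the
   grayscale volume (Otsu by default; a fixed threshold for calibrated
   inputs).
2. **Bone-pair splitting** — the two bones are the two major
   26-connected components ordered along the joint (scan) axis; the
   distal-most is labeled metacarpal head. Components below 1% of the
   bone volume (sesamoid-like satellites) are discarded. A single
   bridged component means bone-on-bone contact; it is routed to a
   programmatic analogue of the operator's coarse head contour
   (`apply_manual_split`), preserving the two-path auto/manual workflow
   and its bookkeeping.
3. **Periosteal filling** — morphological closing with a Euclidean ball
   (default radius 5 voxels) bridges cortical gaps, then 6-connectivity
   hole filling removes trabecular voids. Closing and hole filling are
   exact discrete Minkowski operations computed through distance
   transforms; masks that legitimately span the field of view are not
   eroded at the array border.
4. **Joint-space mask** — see below.
5. **JSW map** — maximal-inscribed-sphere local thickness, in mm.
6. **Summary** — JSV, JSW, JSW.SD, JSW.MIN, JSW.MAX, JSW.AS; ankylotic
   joints flagged, their JSW.AS undefined.
7. **Quality control** — motion grade 4–5, stack-coverage failures and
   ankylosis exclude a joint, with reason precedence motion → coverage
   → ankylosis.
8. **Statistics** — normality-routed two-group tests, chi-squared,
   Spearman correlations, greedy 1:1 sex/age-strata matching, percent
   contrasts and group tables.

## Joint-space mask

The space between the bones is capped by a morphological closing of the
union of both periosteal masks with a **bridging ball (default radius
2.5 mm)**; subtracting the bones and keeping cavity components adjacent
to both bones gives the candidate space. The published description of
the source algorithm stops at "morphological image processing", so the
lateral (marginal) boundary of the joint space is a genuinely open
design point; it is resolved as follows and every parameter is exposed:

- **Pinched-ball coverage.** Inscribed balls of the candidate space
  qualify as articular when they are wedged between the two bones:
  ball surface within 1 voxel of both bones, not clipped by the capping
  surface, nearest-surface directions ≥ 120° apart, and the ball center
  within 1.5 voxels of the chord joining its nearest distal and
  proximal surface points. The chord (collinearity) test is what
  rejects balls pinched against a surface *edge* at the joint margin
  rather than between the articulating surfaces. The reported region is
  the union of qualifying balls.
- **Rim retreat.** The reported region then retreats 3 voxels from its
  open (marginal) edge, where values sit in partial-volume territory.
  Bone-facing boundaries are untouched; for parallel plates the whole
  construction is the identity on the rectangular gap slab.
- **Measuring domain.** Sphere widths are measured in a slightly larger
  domain (the candidate cavity up to a 110° opposition cut, plus all
  qualifying balls in full) so the trim boundary never clips a sphere.

On bone contact the mask carries an ankylosis signal; complete fusion
yields an empty mask.

## Local thickness

The width at a voxel is the diameter of the largest sphere containing
it that fits inside the structure. Sphere centers live on the
**half-voxel lattice**: the mask is upsampled 2× per axis before the
Euclidean distance transform. This calibration makes an *n*-voxel slab
measure exactly *n* voxels for every *n* — with centers restricted to
voxel centers, odd widths are overestimated by one voxel, and the
one-voxel joint space that marks the method's resolution floor would
read 0.164 mm instead of 0.082 mm.

All comparisons are exact integer arithmetic on squared distances. The
implementation prunes candidate spheres contained in a neighbor's
sphere (an exact-output optimisation; containment is transitive and
radius-increasing) and paints the survivors grouped by radius with one
distance transform per distinct radius, restricted to the
still-unassigned region. The test suite holds this path equal, voxel
for voxel, to an exhaustive oracle that enumerates every candidate
sphere from KDTree distances on 200 random connected masks.

JSV is integer voxel-count conservation times the voxel volume; JSW.SD
is the population (divide-by-N) SD of the map — a descriptive summary
of a full map, not a sample estimate. JSW.MIN is the absolute minimum
(no trimming), matching a reported floor of exactly one voxel; a robust
percentile variant can be layered on by callers but is deliberately not
the default.

## Phantoms

The generator emulates two articulating bodies on the native grid
(0.082 mm isotropic voxels, stacks up to 330 slices): parallel and
tilted plates, and a ball-and-cup joint (solid head sphere vs a
spherical-shell sector facing it, cap angle default 70°). Voxelization
is center-sampling. Degradation is Gaussian blur with FWHM defaulting
to 0.130 mm (the effective spatial resolution of the emulated protocol)
plus additive Gaussian noise (default SD 0.05 of the bone/background
contrast — the protocol publishes no grayscale noise magnitude, so the
default is conservative). Phantom gap boundaries for plates are aligned
to voxel boundaries so integer-voxel gaps voxelize exactly.

With an axial center offset *e* the ball-and-cup gap is
`g(θ) = r_c − (sqrt(r_h² − e² sin²θ) + e cosθ)`, extremal at the cap
pole and edge; the ground-truth mean is the area-weighted integral over
the cap. Contact patches fuse a solid-angle (or disc) fraction of the
articulating area; fraction 1 produces a fully ankylotic pair.
Osteophytes are cones attached at the articular rim pointing outward
past the joint margin — the beak-like marginal morphology — so they
never intrude into the articular gap and the analytic gap statistics
remain exact in their presence.

What the phantoms do **not** emulate: scanner physics (beam hardening,
reconstruction kernels), motion artifacts as image content (motion is a
metadata grade), trabecular microarchitecture, and cartilage. Passing
the phantom suite therefore demonstrates geometric and numerical
correctness of the measurement chain, not robustness to every artifact
of real scans.

## Synthetic cohorts

Per-subject, per-joint morphometry is drawn from configured group
normals truncated below at zero by rejection; demographics likewise.
Joints are independent within subject unless an exchangeable
between-joint correlation is supplied (the reference tables publish no
covariance). For parameters whose nominal mean is within ~2 SD of zero
(JSW.MIN and JSW.AS in some groups) rejection truncation shifts the
realized mean upward by construction; recovery tests therefore assert
mean recovery for the parameters with negligible truncation mass (JSV,
JSW, JSW.MAX, JSW.SD), which covers everything the contrast-recovery
check consumes.

## Statistics

Routing follows the study design: Shapiro–Wilk at α = 0.05 per group
(paired: on the differences); normal ⇒ pooled-variance t (paired t),
otherwise Mann–Whitney U — exact when the smaller group has ≤ 8
observations and no ties, mid-rank + normal approximation otherwise —
or Wilcoxon signed-rank. All tests are two-sided; no multiple-testing
correction (the emulated analysis applies none). Spearman ρ is the
Pearson correlation of mid-ranks; its p-value enumerates all n!
orderings for n ≤ 8 and uses the t approximation above. Age strata are
anchored at multiples of 5 years (floor(age/5)·5); within a stratum,
1:1 pairs are chosen greedily by smallest absolute age difference with
lexicographic tie-breaks, which makes matching deterministic and
input-order independent.

## Problem sizes and numerical choices

- Accuracy-suite phantoms sample gaps 0.25–2.5 mm. Curved phantoms are
  gridded so the gap spans at least six voxels (0.041 mm voxels for the
  0.25 mm gap, 0.164 mm voxels for gaps ≥ 1.5 mm with the default head
  radius): below that, the ±1-voxel surface roughness of two voxelized
  curved bodies dominates the width extrema. The accuracy bound is one
  voxel of the grid in use. Plates run at the native grid throughout.
- Oracle-equivalence masks are random connected blobs of extent 10–24
  voxels per axis, 200 of them, fixed seed.
- The resolution-floor experiment uses noiseless phantoms: it
  characterizes the geometric floor of the measurement chain, not noise
  robustness (which the Dice criterion on degraded phantoms covers).
- Ties and degenerate inputs: identical groups or all-zero paired
  differences report p = 1 with a "degenerate" route; constant input to
  Shapiro–Wilk or Spearman is an error/flag, not a silent number.
- Determinism: all randomness flows from explicit integer seeds
  (numpy `default_rng`); identical configuration and inputs give
  byte-identical outputs, and the output bundle records a configuration
  hash.

## Known limitations

- The marginal (rim) trim is a package design decision; measured JSV
  depends on it (plates excepted). Real-scan comparability of absolute
  JSV across implementations is correspondingly limited — contrasts
  between groups measured with the same settings are the intended use.
- The segmentation threshold stand-in (Otsu/fixed) replaces a
  scanner-calibrated filter chain that is not publicly specified.
- Motion grading is an input; no image-based artifact detection.
- Patient-level correlations and p-values of the emulated study cannot
  be reproduced without its raw data; parameter-recovery properties on
  synthetic cohorts stand in for them.
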