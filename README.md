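# articuspace

3D joint-space morphometry of metacarpophalangeal (MCP) joints on
HR-pQCT-like image volumes, built for studying joint-space narrowing in
hereditary hemochromatosis (HH) arthropathy — and for anyone who needs
a tested, fully synthetic-data-validated implementation of
inscribed-sphere joint-space-width mapping.

Hemochromatosis arthropathy characteristically narrows the 2nd and 3rd
MCP joint spaces, sometimes down to the width of a single 82 μm voxel.
Plain radiography under-resolves this. The pipeline implemented here
takes an isotropic CT volume of an MCP joint and computes, per joint:

| parameter | meaning |
|---|---|
| JSV | joint space volume, mm³ |
| JSW | mean local joint-space width, mm |
| JSW.SD | spatial heterogeneity of the width map, mm |
| JSW.MIN / JSW.MAX | extrema of the width map, mm |
| JSW.AS | asymmetry, JSW.MAX / JSW.MIN |

The local width at a voxel is the **maximal-inscribed-sphere (local
thickness)** value: the diameter of the largest sphere containing the
voxel that fits entirely in the joint space,

```
JSW(v) = 2 · max { r : ∃c, v ∈ B(c, r) ⊆ joint space }
```

computed exactly on a half-voxel lattice over the Euclidean distance
transform. Joints in bony contact (ankylosis) are detected and flagged
rather than measured.

Because no patient images are deposited with the study this package
emulates, every stage is validated against **synthetic phantoms with
analytic ground truth** (parallel/tilted plates, ball-and-cup joints,
osteophytes, contact patches, blur and noise) and **synthetic cohorts**
drawn from the published group means ± SD. The statistics stage
reproduces the study design: Shapiro–Wilk-routed two-group tests
(t / Mann–Whitney U, paired t / Wilcoxon), Pearson chi-squared,
tie-safe Spearman correlations with exact permutation p-values at small
n, and greedy 1:1 sex/age matching in 5-year strata.

## Worked example

```python
import numpy as np
from articuspace import GridSpec, PhantomSpec, make_phantom, segment_bone, \
    split_joint_bones, periosteal_mask, BonePairMask
from articuspace.morphometry import measure_joint

# a ball-and-cup joint: 2.5 mm metacarpal head, 1.0 mm joint space
grid = GridSpec((132, 132, 112), voxel_size=0.082)
spec = PhantomSpec("ball_and_cup", gap=1.0, head_radius=2.5, cup_radius=3.5,
                   blur_fwhm=0.0, noise_sd=0.0)
volume, truth_masks, truth = make_phantom(spec, grid)

bone = segment_bone(volume, threshold=0.5)
pair, outcome = split_joint_bones(bone, axis=2, grid=grid)
pair = BonePairMask(periosteal_mask(pair.distal), periosteal_mask(pair.proximal), grid)
morpho, jsw_map = measure_joint(pair)
print(outcome.status, morpho.to_dict())
```

prints

```
auto_success {'jsv_mm3': 36.07049456000001, 'jsw_mm': 0.9799484184506925,
 'jsw_sd_mm': 0.011582390816493341, 'jsw_min_mm': 0.9492186260287986,
 'jsw_max_mm': 1.010963896486912, 'jsw_as': 1.0650485238752998,
 'ankylotic': False}
```

i.e. the measured mean width (0.980 mm) recovers the true 1.0 mm gap
within a fraction of a voxel, the asymmetry of this concentric joint is
≈ 1, and the joint is not ankylotic. A `parallel_plate` phantom with a
one-voxel gap reports `jsw_mm = 0.082` exactly — the method's
resolution floor.

A command-line umbrella `articuspace` wraps the same functionality
(`generate-phantom`, `generate-cohort`, `segment`, `morphometry`, `qc`,
`cohort-stats`, `reproduce-tables`, `run`).

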