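"""Joint-space mask construction, JSW mapping, and the six parameters.

From a pair of periosteal bone masks the intraarticular joint space is
isolated, the local joint-space width (JSW) is mapped by maximal
inscribed spheres, and the map is summarized into the six standard
morphometric parameters: joint space volume (JSV), mean JSW, JSW
heterogeneity (JSW.SD), minimal and maximal JSW (JSW.MIN, JSW.MAX) and
the asymmetry JSW.AS = JSW.MAX / JSW.MIN.

The joint-space mask is built in two steps. A morphological closing of
the union of both bones with a bridging ball (default radius 2.5 mm)
caps the space between the articulating surfaces; subtracting the bones
and keeping the cavity components adjacent to both bones yields the
candidate space. That candidate still carries feather-edged slivers
where the closing surface meets a bone tangentially at the joint
margin, so it is trimmed to its articular core: the region covered by
inscribed balls that are pinched between the two bones (ball surface
within a contact tolerance of both bones, and the directions to the two
nearest bone surfaces roughly opposed). On parallel plates the trim is
the identity — the mask is exactly the rectangular gap slab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _morphology as morph
from .grid import BonePairMask, GridSpec
from .thickness import local_thickness_map

__all__ = [
    "JointSpaceMask",
    "JSWMap",
    "JointMorphometry",
    "build_joint_space_mask",
    "compute_jsw_map",
    "summarize_morphometry",
    "measure_joint",
]

#: Default bridging-ball radius for capping the joint space, mm.
DEFAULT_BRIDGING_RADIUS_MM = 2.5

#: A covering ball counts as touching a bone if its surface comes
#: within this many voxels of it.
CONTACT_TOL_VOX = 1.0

#: Nearest-surface directions must be at least 120 degrees apart for a
#: ball to count as pinched between the bones (cos threshold).
OPPOSITION_COS = -0.5

#: Looser opposition threshold (110 degrees) bounding the *measuring
#: domain* the inscribed spheres may occupy beyond the reported region.
DOMAIN_OPPOSITION_COS = -0.342

#: The reported region retreats this many voxels from its open
#: (marginal) edge; bone-facing boundaries are unaffected.
RIM_MARGIN_VOX = 3.0


@dataclass
class JointSpaceMask:
    """Binary mask of the intraarticular space between two bones.

    ``mask`` is the articular region the parameters are read from;
    ``cavity`` (when present) is the untrimmed capped joint space the
    inscribed spheres are measured in, so that the trim boundary never
    clips a sphere.
    """

    mask: np.ndarray
    grid: GridSpec
    ankylotic_contact: bool = False
    cavity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("joint-space mask shape does not match grid")
        if self.cavity is not None:
            self.cavity = np.asarray(self.cavity, dtype=bool)
            if self.cavity.shape != self.grid.shape:
                raise ValueError("cavity shape does not match grid")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class JSWMap:
    """Per-voxel local joint-space width in mm on the mask support."""

    values: np.ndarray
    space: JointSpaceMask

    def in_mask_values(self) -> np.ndarray:
        return self.values[self.space.mask]


@dataclass
class JointMorphometry:
    """The six joint-space parameters plus the ankylosis flag.

    ``jsw_as`` is NaN (undefined) for ankylotic joints, which are
    flagged for exclusion downstream.
    """

    jsv_mm3: float
    jsw_mm: float
    jsw_sd_mm: float
    jsw_min_mm: float
    jsw_max_mm: float
    jsw_as: float
    ankylotic: bool = False

    def to_dict(self) -> dict:
        return {
            "jsv_mm3": self.jsv_mm3,
            "jsw_mm": self.jsw_mm,
            "jsw_sd_mm": self.jsw_sd_mm,
            "jsw_min_mm": self.jsw_min_mm,
            "jsw_max_mm": self.jsw_max_mm,
            "jsw_as": self.jsw_as,
            "ankylotic": self.ankylotic,
        }


def _cover_with_balls(centers: np.ndarray, r2: np.ndarray, domain: np.ndarray) -> np.ndarray:
    """Union of open balls ``{v : |v-y|^2 < r2(y)}`` over center voxels,
    intersected with ``domain``."""
    out = np.zeros(domain.shape, dtype=bool)
    todo = domain.copy()
    for q in np.unique(r2[centers])[::-1]:
        if not todo.any():
            break
        s_q = centers & (r2 == q)
        pad = int(math.ceil(math.sqrt(q))) + 1
        idx = np.nonzero(s_q)
        lo = [max(int(i.min()) - pad, 0) for i in idx]
        hi = [min(int(i.max()) + pad + 1, n) for i, n in zip(idx, domain.shape)]
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        if not todo[box].any():
            continue
        d = ndimage.distance_transform_edt(~s_q[box])
        hit = (np.rint(d * d).astype(np.int64) < q) & todo[box]
        out[box] |= hit
        todo[box] &= ~hit
    return out


def build_joint_space_mask(
    bones: BonePairMask,
    bridging_radius_mm: float = DEFAULT_BRIDGING_RADIUS_MM,
    contact_tol_vox: float = CONTACT_TOL_VOX,
    opposition_cos: float = OPPOSITION_COS,
    rim_margin_vox: float = RIM_MARGIN_VOX,
    domain_cos: float = DOMAIN_OPPOSITION_COS,
) -> JointSpaceMask:
    """Isolate the intraarticular space between the two periosteal masks.

    Raises ``ValueError("no joint space")`` when disjoint, facing bones
    yield an empty space. When the bones are in contact the returned
    mask carries ``ankylotic_contact=True``; if the contact is complete
    (no residual space) the mask is empty.
    """
    grid = bones.grid
    h = grid.voxel_size
    contact = morph.masks_touch(bones.distal, bones.proximal)

    union = bones.union
    r_vox = bridging_radius_mm / h
    candidate = morph.ball_close(union, r_vox) & ~union

    if candidate.any():
        labels, _ = morph.label_components(candidate)
        grown = np.ones((3, 3, 3), dtype=bool)
        near_d = set(np.unique(labels[ndimage.binary_dilation(bones.distal, grown)])) - {0}
        near_p = set(np.unique(labels[ndimage.binary_dilation(bones.proximal, grown)])) - {0}
        keep = near_d & near_p
        candidate &= np.isin(labels, sorted(keep))

    if candidate.any():
        # Work in the candidate bounding box (padded so nearest-bone
        # lookups stay correct) to bound EDT cost on large grids.
        pad = int(math.ceil(r_vox)) + 2
        idx = np.nonzero(candidate)
        lo = [max(int(i.min()) - pad, 0) for i in idx]
        hi = [min(int(i.max()) + pad + 1, n) for i, n in zip(idx, grid.shape)]
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        cand = candidate[box]
        distal, proximal = bones.distal[box], bones.proximal[box]

        r = ndimage.distance_transform_edt(cand)
        r2 = np.rint(r * r).astype(np.int64)
        dd, ind_d = ndimage.distance_transform_edt(~distal, return_indices=True)
        dp, ind_p = ndimage.distance_transform_edt(~proximal, return_indices=True)
        coords = np.indices(cand.shape)
        vd = ind_d - coords
        vp = ind_p - coords
        dot = (vd * vp).sum(axis=0)
        norm = np.sqrt((vd * vd).sum(axis=0).astype(np.float64)
                       * (vp * vp).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_ang = np.where(norm > 0, dot / np.maximum(norm, 1e-300), 1.0)
        # Distance from the voxel to the chord joining its nearest
        # distal and proximal surface points: a ball genuinely wedged
        # between the bones sits on that chord, whereas balls pinched
        # against a surface *edge* at the joint margin do not.
        chord = vp - vd  # nd -> np, both relative to the voxel
        chord_len2 = (chord * chord).sum(axis=0).astype(np.float64)
        t = np.clip(
            -(vd * chord).sum(axis=0) / np.maximum(chord_len2, 1e-300), 0.0, 1.0
        )
        closest = vd + t * chord
        seg_dist = np.sqrt((closest * closest).sum(axis=0))
        pinched = (
            cand
            & (dd <= r + contact_tol_vox)
            & (dp <= r + contact_tol_vox)
            # The ball must actually reach the nearer bone, i.e. not be
            # clipped by the capping (closing) surface at the margin.
            & (r >= np.minimum(dd, dp) - 0.5)
            & (cos_ang <= opposition_cos)
            & (seg_dist <= 1.5)
        )
        space = np.zeros(grid.shape, dtype=bool)
        domain = np.zeros(grid.shape, dtype=bool)
        if pinched.any():
            cover = _cover_with_balls(pinched, r2, cand)
            sup = cover.copy()
            # Retreat from the open (marginal) edge: values there sit in
            # partial-volume territory at the articular margin.
            open_region = cand & ~cover
            if open_region.any() and rim_margin_vox > 0:
                d_open = ndimage.distance_transform_edt(~open_region)
                sup &= d_open > rim_margin_vox
            space[box] = sup
            # The measuring domain must contain every covering ball in
            # full, plus the opposed part of the cavity, so the trim
            # never clips a sphere.
            domain[box] = (cand & (cos_ang <= domain_cos)) | cover
    else:
        space = np.zeros(grid.shape, dtype=bool)
        domain = space

    if not space.any() and not contact:
        raise ValueError("no joint space")
    return JointSpaceMask(mask=space, grid=grid, ankylotic_contact=contact,
                          cavity=domain)


def compute_jsw_map(space: JointSpaceMask) -> JSWMap:
    """Local JSW map: per voxel, the diameter (mm) of the largest sphere
    inside the joint space that covers the voxel."""
    if not space.mask.any():
        raise ValueError("empty joint space")
    if space.cavity is not None and space.cavity.any():
        # Spheres are inscribed in the measuring domain (the articular
        # cavity up to the 110-degree opposition cut), so the trim
        # boundary of the reported region never clips a sphere.
        values = local_thickness_map(
            space.cavity | space.mask, space.grid.voxel_size, support=space.mask
        )
    else:
        values = local_thickness_map(space.mask, space.grid.voxel_size)
    return JSWMap(values=values, space=space)


def summarize_morphometry(
    jsw_map: JSWMap,
    space: JointSpaceMask | None = None,
    grid: GridSpec | None = None,
    ankylotic_contact: bool | None = None,
) -> JointMorphometry:
    """Summarize a JSW map into the six morphometric parameters.

    JSV is exactly (voxel count of the mask) x voxel volume; JSW.SD is
    the population (divide-by-N) SD of the map values. For ankylotic
    joints JSW.AS is undefined (NaN) and the joint is flagged.
    """
    space = space if space is not None else jsw_map.space
    grid = grid if grid is not None else space.grid
    if ankylotic_contact is None:
        ankylotic_contact = space.ankylotic_contact
    vals = jsw_map.values[space.mask]
    if vals.size == 0:
        raise ValueError("empty joint space")
    jsv = space.voxel_count * grid.voxel_volume
    jsw_min = float(vals.min())
    ankylotic = bool(ankylotic_contact) or jsw_min <= 0.0
    return JointMorphometry(
        jsv_mm3=float(jsv),
        jsw_mm=float(vals.mean()),
        jsw_sd_mm=float(vals.std(ddof=0)),
        jsw_min_mm=jsw_min,
        jsw_max_mm=float(vals.max()),
        jsw_as=float("nan") if ankylotic else float(vals.max() / jsw_min),
        ankylotic=ankylotic,
    )


def measure_joint(
    bones: BonePairMask,
    bridging_radius_mm: float = DEFAULT_BRIDGING_RADIUS_MM,
) -> tuple[JointMorphometry, JSWMap]:
    """Convenience chain: joint-space mask -> JSW map -> six parameters."""
    space = build_joint_space_mask(bones, bridging_radius_mm=bridging_radius_mm)
    if not space.mask.any():
        # Complete ankylosis: no measurable space.
        return (
            JointMorphometry(0.0, float("nan"), float("nan"), float("nan"),
                             float("nan"), float("nan"), ankylotic=True),
            JSWMap(values=np.zeros(bones.grid.shape), space=space),
        )
    jsw_map = compute_jsw_map(space)
    return summarize_morphometry(jsw_map), jsw_map
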