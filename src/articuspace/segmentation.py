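"""Bone segmentation: threshold, bone-pair splitting, periosteal filling.

The workflow mirrors a semi-automated joint pipeline: mineralized bone
is thresholded from the grayscale volume, the two bones of the joint are
identified as the two major connected components along the joint axis,
and each is converted to a filled periosteal mask. When the bones are in
direct contact (a bridged component, as happens with localized complete
joint-space loss) the automatic split fails and the programmatic
analogue of the operator's coarse head contour — ``apply_manual_split``
— separates them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from . import _morphology as morph
from .grid import BonePairMask, GridSpec, VolumeImage

__all__ = [
    "SegmentationOutcome",
    "segment_bone",
    "split_joint_bones",
    "apply_manual_split",
    "periosteal_mask",
]

#: Components smaller than this fraction of the total bone volume are
#: discarded as sesamoid-like satellites.
MAJOR_COMPONENT_FRACTION = 0.01

#: Default closing-ball radius (voxels) for periosteal filling.
DEFAULT_PERIOSTEAL_RADIUS_VOX = 5.0


@dataclass
class SegmentationOutcome:
    """Bookkeeping of one joint's segmentation attempt."""

    status: str  # "auto_success" | "needs_manual" | "failed"
    reason: str = ""
    attempts: int = 1

    def to_dict(self) -> dict:
        return {"status": self.status, "reason": self.reason, "attempts": self.attempts}


def segment_bone(volume: VolumeImage, threshold: str | float = "otsu") -> np.ndarray:
    """Binary mask of mineralized bone.

    ``threshold`` is either a fixed intensity or ``"otsu"`` for the
    histogram-derived threshold. Deterministic for fixed input.
    """
    values = volume.values
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold strategy {threshold!r}")
        if np.all(values == values.flat[0]):
            raise ValueError("degenerate histogram: constant image")
        t = float(threshold_otsu(values))
    else:
        t = float(threshold)
    mask = values > t
    if not mask.any():
        raise ValueError("no bone found")
    return mask


def split_joint_bones(
    bone_mask: np.ndarray, axis: int = 2, grid: GridSpec | None = None
) -> tuple[BonePairMask | None, SegmentationOutcome]:
    """Split a bone mask into the distal/proximal pair along ``axis``.

    Exactly two major 26-connected components: the distal-most (lower
    centroid along the joint axis) becomes the metacarpal head, the
    other the phalangeal base; satellites below 1% of the bone volume
    (sesamoid-like) are discarded. One bridged component means the bones
    are in contact and a manual split is required.
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if not bone_mask.any():
        raise ValueError("no bone found")
    labels, n = morph.label_components(bone_mask)
    sizes = np.bincount(labels.ravel())[1:]
    total = sizes.sum()
    major = [i + 1 for i, s in enumerate(sizes) if s >= MAJOR_COMPONENT_FRACTION * total]
    if len(major) == 1:
        return None, SegmentationOutcome(status="needs_manual", reason="bridged")
    if len(major) != 2:
        raise ValueError(f"ambiguous joint: {len(major)} major components")
    grid_shape = bone_mask.shape

    def centroid_along(lab: int) -> float:
        return float(np.mean(np.nonzero(labels == lab)[axis]))

    a, b = sorted(major, key=centroid_along)
    if grid is None:
        grid = GridSpec(shape=grid_shape, voxel_size=1.0)
    pair = BonePairMask(distal=labels == a, proximal=labels == b, grid=grid)
    return pair, SegmentationOutcome(status="auto_success", reason="")


def apply_manual_split(
    bone_mask: np.ndarray, head_contour: np.ndarray, grid: GridSpec | None = None
) -> BonePairMask:
    """Separate a bridged bone mask with a coarse head contour.

    Bone voxels inside ``head_contour`` (a boolean volume, the
    programmatic analogue of the operator's circled metacarpal head)
    become the distal bone, the remainder the proximal bone.
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    head_contour = np.asarray(head_contour, dtype=bool)
    if head_contour.shape != bone_mask.shape:
        raise ValueError("contour shape does not match mask")
    distal = bone_mask & head_contour
    proximal = bone_mask & ~head_contour
    if not distal.any() or not proximal.any():
        raise ValueError("non-separating contour")
    if grid is None:
        grid = GridSpec(shape=bone_mask.shape, voxel_size=1.0)
    return BonePairMask(distal=distal, proximal=proximal, grid=grid)


def periosteal_mask(
    bone_mask: np.ndarray, closing_radius_vox: float = DEFAULT_PERIOSTEAL_RADIUS_VOX
) -> np.ndarray:
    """Filled periosteal mask of one bone.

    Morphological closing with a Euclidean ball (default radius 5
    voxels) bridges trabecular gaps in the cortex, then 6-connectivity
    hole filling removes internal cavities. The operation is extensive
    (output contains input) and idempotent; the outer surface moves by
    at most the closing radius.
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if not bone_mask.any():
        raise ValueError("no bone found")
    closed = morph.ball_close(bone_mask, closing_radius_vox)
    return morph.fill_holes(closed)
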