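"""Inclusion/exclusion rules and segmentation-success bookkeeping.

Joints are excluded when motion artifacts make the scan unusable
(visual motion grade 4-5 on the 1-5 Pialat scale), when the joint
surfaces are not fully contained in the slice stack, or when the joint
is ankylotic. Exclusion reasons follow the fixed precedence
motion -> coverage -> ankylosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import BonePairMask, GridSpec
from .segmentation import SegmentationOutcome

__all__ = [
    "QualityRecord",
    "apply_inclusion_rules",
    "check_joint_coverage",
    "tally_success_rates",
]

JOINTS = ("MCP2", "MCP3", "MCP4")

#: A bone-surface voxel counts as articular when the other bone is
#: within this distance (mm); shaft surfaces far from the joint are not.
DEFAULT_FACING_DISTANCE_MM = 2.5


@dataclass
class QualityRecord:
    """Per-joint quality metadata feeding the inclusion rules.

    ``motion_grade`` is the 1-5 visual motion score (an input, not
    computed from image content); ``coverage_ok`` flags whether both
    articulating surfaces are fully inside the slice stack.
    """

    subject_id: str
    joint: str
    motion_grade: int = 1
    coverage_ok: bool = True
    ankylotic: bool = False
    outcome: SegmentationOutcome | None = None

    def __post_init__(self) -> None:
        if self.motion_grade not in (1, 2, 3, 4, 5):
            raise ValueError("motion_grade must be an integer in 1..5")


def apply_inclusion_rules(
    records: list[QualityRecord],
) -> tuple[list[QualityRecord], list[dict]]:
    """Split records into included joints and an exclusion log.

    Excluded: motion grade 4-5, coverage failures, ankylotic joints —
    one reason per exclusion, first matching rule in the order
    motion -> coverage -> ankylosis. Deterministic and independent of
    record order.
    """
    included: list[QualityRecord] = []
    log: list[dict] = []
    for rec in records:
        if rec.motion_grade >= 4:
            reason = "motion"
        elif not rec.coverage_ok:
            reason = "coverage"
        elif rec.ankylotic:
            reason = "ankylosis"
        else:
            included.append(rec)
            continue
        log.append({"subject_id": rec.subject_id, "joint": rec.joint, "reason": reason})
    return included, log


def check_joint_coverage(
    bones: BonePairMask,
    grid: GridSpec | None = None,
    axis: int = 2,
    facing_distance_mm: float = DEFAULT_FACING_DISTANCE_MM,
) -> bool:
    """True iff neither articulating surface touches the stack ends.

    The articulating surface of each bone is the set of its surface
    voxels lying within ``facing_distance_mm`` of the other bone; a
    lateral shaft touching the stack end does not fail coverage.
    """
    grid = grid if grid is not None else bones.grid
    tol_vox = facing_distance_mm / grid.voxel_size
    cross = ndimage.generate_binary_structure(3, 1)
    for mask, other in ((bones.distal, bones.proximal), (bones.proximal, bones.distal)):
        # border_value=0 so a face lying on the stack boundary counts
        # as surface — that is exactly the truncation to detect.
        surface = mask & ~ndimage.binary_erosion(mask, structure=cross, border_value=0)
        d_other = ndimage.distance_transform_edt(~other)
        articular = surface & (d_other <= tol_vox)
        if not articular.any():
            continue
        k = np.nonzero(articular)[axis]
        if k.min() == 0 or k.max() == grid.shape[axis] - 1:
            return False
    return True


def tally_success_rates(records: list[QualityRecord]) -> dict:
    """Per-joint and overall segmentation success percentages.

    Percentages are 100 * count / denominator rounded to one decimal;
    denominators are the included joints per stratum. Because it is not
    self-evident whether ankylotic joints should be counted in the
    denominator before or after grading, both denominators are
    reported (``n`` excludes them, ``n_with_ankylotic`` does not).
    """
    if not records:
        raise ValueError("empty record list")
    included, _ = apply_inclusion_rules(records)
    with_anky, _ = apply_inclusion_rules(
        [
            QualityRecord(r.subject_id, r.joint, r.motion_grade, r.coverage_ok, False, r.outcome)
            for r in records
        ]
    )

    def stratum(recs: list[QualityRecord], n_alt: int) -> dict:
        n = len(recs)
        auto = sum(1 for r in recs if r.outcome is not None and r.outcome.status == "auto_success")
        manual = sum(1 for r in recs if r.outcome is not None and r.outcome.status == "needs_manual")
        return {
            "n": n,
            "n_with_ankylotic": n_alt,
            "auto_success": auto,
            "needs_manual": manual,
            "pct_auto": round(100.0 * auto / n, 1) if n else float("nan"),
            "pct_manual": round(100.0 * manual / n, 1) if n else float("nan"),
        }

    out = {"overall": stratum(included, len(with_anky))}
    for joint in sorted({r.joint for r in records}):
        out[joint] = stratum(
            [r for r in included if r.joint == joint],
            len([r for r in with_anky if r.joint == joint]),
        )
    return out
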