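"""Euclidean-ball morphology built on exact distance transforms.

scipy's structuring-element morphology erodes at the array border (it
pads with background), which is wrong for bone masks that legitimately
span the full lateral field of view. The helpers here implement
dilation/erosion/closing with a Euclidean ball via distance transforms,
treating everything outside the array as foreground-compatible: a mask
touching the border is not eaten from that side.

All comparisons are done on integer squared distances so results are
exact discrete Minkowski operations with the ball
``B_r = {offset : |offset|^2 <= r^2}``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def squared_edt(background: np.ndarray) -> np.ndarray:
    """Integer squared Euclidean distance to the nearest True voxel of
    ``background`` (0 where background itself).

    Distances are voxel-center to voxel-center in voxel units. With no
    True voxel at all the distance is unbounded (scipy's EDT is
    undefined there), represented by a large sentinel.
    """
    background = np.asarray(background, dtype=bool)
    if not background.any():
        return np.full(background.shape, np.iinfo(np.int64).max // 4, dtype=np.int64)
    d = ndimage.distance_transform_edt(~background)
    return np.rint(d * d).astype(np.int64)


def ball_dilate(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Minkowski dilation by the Euclidean ball of the given radius."""
    if radius_vox <= 0:
        return np.asarray(mask, dtype=bool).copy()
    d2 = squared_edt(mask)
    return d2 <= radius_vox * radius_vox


def ball_erode(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Minkowski erosion by the Euclidean ball; outside the array is
    treated as foreground (border-preserving)."""
    mask = np.asarray(mask, dtype=bool)
    if radius_vox <= 0:
        return mask.copy()
    d2 = squared_edt(~mask)
    return d2 > radius_vox * radius_vox


def ball_close(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Morphological closing with a Euclidean ball (exact, idempotent)."""
    return ball_erode(ball_dilate(mask, radius_vox), radius_vox)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill internal cavities using 6-connectivity for the background."""
    return ndimage.binary_fill_holes(mask)


def label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components under 26-connectivity."""
    return ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))


def masks_touch(a: np.ndarray, b: np.ndarray) -> bool:
    """True when the two masks overlap or are 26-adjacent."""
    if np.any(a & b):
        return True
    grown = ndimage.binary_dilation(a, structure=np.ones((3, 3, 3), dtype=bool))
    return bool(np.any(grown & b))
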