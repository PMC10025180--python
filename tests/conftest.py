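"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from articuspace import GridSpec, PhantomSpec, make_phantom
from articuspace.thickness import upsample2


def make_plate(gap_mm: float, voxel: float = 0.082, lateral: int = 50,
               blur: float = 0.0, noise: float = 0.0, seed: int = 0, **kw):
    """Parallel-plate phantom with sensible grid sizing."""
    nz = int(np.ceil((2 * 1.5 + gap_mm) / voxel)) + 16
    grid = GridSpec((lateral, lateral, nz), voxel)
    spec = PhantomSpec("parallel_plate", gap=gap_mm, blur_fwhm=blur,
                       noise_sd=noise, seed=seed, **kw)
    return make_phantom(spec, grid) + (grid,)


def make_ball(gap_mm: float, voxel: float = 0.082, head: float = 2.5,
              offset: float = 0.0, **kw):
    """Ball-and-cup phantom; cup radius = head + gap."""
    cup = head + gap_mm
    wall = 0.6 * head
    extent = 2 * (cup + wall) + 0.8
    n = int(np.ceil(extent / voxel))
    nz = int(np.ceil((head + cup + wall + 1.0) / voxel)) + 8
    grid = GridSpec((n, n, nz), voxel)
    spec = PhantomSpec("ball_and_cup", gap=gap_mm, head_radius=head,
                       cup_radius=cup, cup_wall=wall, center_offset=offset,
                       blur_fwhm=0.0, noise_sd=0.0, **kw)
    return make_phantom(spec, grid) + (grid,)


def oracle_q_map(mask: np.ndarray) -> np.ndarray:
    """Brute-force maximal-inscribed-sphere squared-radius map.

    Independent of the implementation: the mask is upsampled to the
    half-voxel lattice, per-voxel squared radii come from KDTree
    distances to the background, and every candidate ball is painted
    explicitly (no pruning, no grouped distance transforms).
    """
    fine = upsample2(np.asarray(mask, dtype=bool))
    pts = np.argwhere(fine)
    bg = np.argwhere(~fine)
    out = np.zeros(fine.shape, dtype=np.int64)
    if pts.size == 0:
        return out
    if bg.size == 0:
        r2 = np.full(len(pts), np.iinfo(np.int64).max // 4)
    else:
        d, _ = cKDTree(bg).query(pts)
        r2 = np.rint(d * d).astype(np.int64)
    in_tree = cKDTree(pts)
    flat = out.reshape(-1)
    strides = np.array([fine.shape[1] * fine.shape[2], fine.shape[2], 1])
    for i in range(len(pts)):
        q = r2[i]
        # strict |v - y|^2 < q with integer squared distances: radius
        # sqrt(q - 0.5) includes exactly d^2 <= q - 1
        idx = in_tree.query_ball_point(pts[i], np.sqrt(q - 0.5))
        lin = pts[idx] @ strides
        flat[lin] = np.maximum(flat[lin], q)
    return out


def random_connected_mask(rng: np.random.Generator, size: int, fill: float = 0.45
                          ) -> np.ndarray:
    """Random connected blob of the given cubic extent."""
    noise = rng.random((size, size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=1.5)
    mask = smooth > np.quantile(smooth, 1.0 - fill)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        mask = np.zeros((size, size, size), bool)
        mask[size // 2, size // 2, size // 2] = True
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (1 + int(np.argmax(sizes)))


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    cross = ndimage.generate_binary_structure(3, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=cross, border_value=1)


def brute_force_gap_stats(distal: np.ndarray, proximal: np.ndarray,
                          voxel: float, articular_of: np.ndarray | None = None):
    """Nearest-surface distances between the two bones.

    Returns (min, max) of the per-voxel distance from each distal
    articular-surface voxel to the nearest proximal voxel, converted to
    a surface-to-surface gap (center distance minus one voxel for the
    two half-voxel shells).
    """
    surf = surface_voxels(distal)
    if articular_of is not None:
        surf &= articular_of
    src = np.argwhere(surf)
    tgt = np.argwhere(proximal)
    d, _ = cKDTree(tgt).query(src)
    gaps = (d - 1.0) * voxel
    return float(gaps.min()), float(gaps.max())


def mwu_enumeration_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating group labelings."""
    import itertools

    from scipy import stats as sps

    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    u_obs = min(u_obs, n * m - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2
        u = min(u, n * m - u)
        count += u <= u_obs + 1e-12
        total += 1
    return count / total


def spearman_enumeration_p(x, y):
    """Two-sided exact Spearman p for tie-free data via the classical
    sum-of-squared-rank-differences formula over all n! permutations."""
    import itertools

    from scipy import stats as sps

    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    denom = n * (n * n - 1)
    rho_obs = abs(1 - 6 * np.sum((rx - ry) ** 2) / denom)
    perms = np.array(list(itertools.permutations(range(n))))
    d2 = ((rx[None, :] - ry[perms]) ** 2).sum(axis=1)
    rhos = np.abs(1 - 6 * d2 / denom)
    return float(np.mean(rhos >= rho_obs - 1e-12))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
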