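"""Joint-space mask and the six morphometric parameters."""

import math

import numpy as np
import pytest

from articuspace import (
    GridSpec,
    JointSpaceMask,
    JSWMap,
    PhantomSpec,
    add_contact_patch,
    build_joint_space_mask,
    compute_jsw_map,
    make_phantom,
    summarize_morphometry,
)
from articuspace.grid import BonePairMask
from articuspace.morphometry import measure_joint

from conftest import make_ball, make_plate


class TestBuildJointSpaceMask:
    def test_plate_gap_is_exact_rectangular_slab(self):
        """Facing area 50 x 50, gap 12 voxels, bridging radius larger
        than the gap: the mask is exactly the 50 x 50 x 12 slab."""
        vol, masks, gt, grid = make_plate(12 * 0.082)
        space = build_joint_space_mask(masks)
        assert space.voxel_count == 50 * 50 * 12
        z = np.nonzero(space.mask.any(axis=(0, 1)))[0]
        assert len(z) == 12
        assert space.mask[:, :, z.min():z.max() + 1].all()

    def test_fully_ankylotic_pair_is_empty_with_signal(self):
        spec = add_contact_patch(
            PhantomSpec("parallel_plate", gap=1.0, blur_fwhm=0, noise_sd=0), 1.0
        )
        grid = GridSpec((40, 40, 70), 0.082)
        vol, masks, gt = make_phantom(spec, grid)
        space = build_joint_space_mask(masks)
        assert space.ankylotic_contact
        assert space.voxel_count == 0

    def test_distant_bones_raise_no_joint_space(self):
        """Bones farther apart than the bridging reach do not form a
        joint space."""
        grid = GridSpec((30, 30, 120), 0.082)
        vol, masks, gt, _ = make_plate(6.0, lateral=30)
        with pytest.raises(ValueError, match="no joint space"):
            build_joint_space_mask(masks, bridging_radius_mm=1.0)

    def test_concentric_cup_mask_lies_between_the_surfaces(self):
        vol, masks, gt, grid = make_ball(1.0, head=2.0)
        space = build_joint_space_mask(masks)
        h = grid.voxel_size
        n, _, nz = grid.shape
        # head 2.0, cup 3.0, wall 1.2 (0.6 * head): center placement as
        # in the generator
        z_head = (nz * h) / 2.0 - (3.0 + 1.2 - 2.0) / 2.0
        idx = np.argwhere(space.mask)
        c = np.array([n * h / 2, n * h / 2, z_head])
        rad = np.linalg.norm((idx + 0.5) * h - c, axis=1)
        assert rad.min() >= 2.0 - h
        assert rad.max() <= 3.0 + h


class TestComputeJSWMap:
    def test_plate_gap_within_half_voxel(self):
        vol, masks, gt, grid = make_plate(1.0)
        space = build_joint_space_mask(masks)
        jsw = compute_jsw_map(space)
        vals = jsw.in_mask_values()
        assert np.all(np.abs(vals - 1.0) <= 0.041 + 1e-12)

    def test_concentric_cup_central_cap_within_one_voxel(self):
        vol, masks, gt, grid = make_ball(1.0, head=2.0)
        space = build_joint_space_mask(masks)
        jsw = compute_jsw_map(space)
        vals = jsw.in_mask_values()
        assert np.mean(np.abs(vals - 1.0) <= 0.082) >= 0.8

    def test_empty_mask_rejected(self):
        grid = GridSpec((10, 10, 10), 0.082)
        space = JointSpaceMask(mask=np.zeros(grid.shape, bool), grid=grid,
                               ankylotic_contact=True)
        with pytest.raises(ValueError, match="empty joint space"):
            compute_jsw_map(space)


class TestSummarize:
    def _space_and_map(self, values, voxel=0.1):
        n = len(values)
        side = int(np.ceil(n ** (1 / 3))) + 1
        grid = GridSpec((max(side, 4), max(side, 4), max(4, n // (side * side) + 2)), voxel)
        mask = np.zeros(grid.shape, bool)
        flat = np.zeros(grid.shape)
        filled = 0
        it = np.ndindex(grid.shape)
        for pos in it:
            if filled == n:
                break
            mask[pos] = True
            flat[pos] = values[filled]
            filled += 1
        space = JointSpaceMask(mask=mask, grid=grid)
        return JSWMap(values=flat, space=space)

    def test_constant_map(self):
        jm = self._space_and_map([1.2] * 1000, voxel=0.1)
        m = summarize_morphometry(jm)
        assert m.jsv_mm3 == pytest.approx(1.0)
        assert m.jsw_mm == pytest.approx(1.2)
        assert m.jsw_min_mm == pytest.approx(1.2)
        assert m.jsw_max_mm == pytest.approx(1.2)
        assert m.jsw_sd_mm == pytest.approx(0.0, abs=1e-12)
        assert m.jsw_as == pytest.approx(1.0)

    def test_asymmetry_is_max_over_min(self):
        jm = self._space_and_map([0.6, 1.0, 2.4, 1.5])
        m = summarize_morphometry(jm)
        assert m.jsw_as == pytest.approx(4.0)

    def test_single_voxel_gap_mean_is_one_voxel(self):
        """The narrowest measurable joint space: one 0.082 mm voxel."""
        vol, masks, gt, grid = make_plate(0.082, lateral=30)
        morpho, _ = measure_joint(masks)
        assert morpho.jsw_mm == pytest.approx(0.082, abs=1e-12)

    def test_ankylotic_contact_flags_and_undefines_asymmetry(self):
        jm = self._space_and_map([0.5, 0.7])
        m = summarize_morphometry(jm, ankylotic_contact=True)
        assert m.ankylotic
        assert math.isnan(m.jsw_as)


class TestInvariantsOnPhantoms:
    def test_jsv_is_exact_voxel_count_conservation(self):
        for gap in (0.25, 1.0):
            vol, masks, gt, grid = make_plate(gap, lateral=30)
            morpho, jsw = measure_joint(masks)
            assert morpho.jsv_mm3 == jsw.space.voxel_count * grid.voxel_volume

    def test_mean_jsw_monotone_in_gap(self):
        means = []
        for gap in (0.25, 0.5, 1.0, 1.5):
            vol, masks, gt, grid = make_plate(gap, lateral=30)
            morpho, _ = measure_joint(masks)
            means.append(morpho.jsw_mm)
            assert morpho.jsw_max_mm <= gap + 0.082 + 1e-12
        assert means == sorted(means)
        assert len(set(means)) == len(means)

    def test_rotation_invariance_of_all_six_parameters(self):
        vol, masks, gt, grid = make_plate(0.5, lateral=26)
        base, _ = measure_joint(masks)
        rot = BonePairMask(
            distal=np.rot90(masks.distal, k=1, axes=(0, 1)),
            proximal=np.rot90(masks.proximal, k=1, axes=(0, 1)),
            grid=grid,
        )
        m, _ = measure_joint(rot)
        for field in ("jsv_mm3", "jsw_mm", "jsw_sd_mm", "jsw_min_mm", "jsw_max_mm", "jsw_as"):
            assert getattr(m, field) == getattr(base, field)
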