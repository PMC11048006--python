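"""Geometry of the core/periphery decomposition."""

import numpy as np
import pytest

from conftest import make_ball, random_blob
from oracles import brute_force_boundary_distance, brute_force_core
from subgrade.subregions import (
    AlignmentError,
    CORE_FRACTIONS,
    DegenerateRegionError,
    EmptyMaskError,
    VoxelMask,
    boundary_distance,
    build_subregion_set,
    dice,
    extract_core,
    extract_periphery,
)


class TestBoundaryDistance:
    def test_isolated_voxel_has_unit_distance(self):
        grid = np.zeros((5, 5, 5), dtype=bool)
        grid[2, 2, 2] = True
        d = boundary_distance(VoxelMask(grid, (1, 1, 1)))
        assert d[2, 2, 2] == pytest.approx(1.0)
        assert d[0, 0, 0] == 0.0

    def test_ball_max_depth_close_to_radius(self, ball10):
        d = boundary_distance(ball10)
        assert abs(d.max() - 10.0) <= 1.0

    def test_anisotropic_slab_reflects_z_spacing(self):
        # a one-voxel-thick slab at spacing (1,1,3): the out-of-plane escape
        # costs 3 mm, so interior depth is min(in-plane distance, 3)
        grid = np.zeros((7, 7, 1), dtype=bool)
        grid[1:6, 1:6, 0] = True
        d = boundary_distance(VoxelMask(grid, (1, 1, 3)))
        assert d[1, 1, 0] == pytest.approx(1.0)  # in-plane edge wins
        assert d[3, 3, 0] == pytest.approx(3.0)  # z-step wins at the centre
        assert d.max() == pytest.approx(3.0)

    def test_matches_brute_force_oracle(self, rng):
        mask = random_blob(rng, n=12, spacing=(1.0, 1.5, 2.0))
        expected = brute_force_boundary_distance(mask.grid, mask.spacing_mm)
        np.testing.assert_allclose(boundary_distance(mask), expected, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            boundary_distance(VoxelMask(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1)))


class TestExtractCore:
    def test_fraction_one_is_identity(self, ball8):
        assert extract_core(ball8, 1.0) is ball8

    def test_ball_half_core_count_and_shape(self, ball10):
        core = extract_core(ball10, 0.50)
        assert core.count == round(0.50 * ball10.count)
        # deepest voxels form one connected lump containing the centroid
        from scipy import ndimage

        assert ndimage.label(core.grid)[1] == 1
        centroid = tuple(int(round(c)) for c in np.argwhere(ball10.grid).mean(axis=0))
        assert core.grid[centroid]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sort_by_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob(rng, n=14)
        for frac in CORE_FRACTIONS:
            expected = brute_force_core(mask.grid, mask.spacing_mm, frac)
            got = extract_core(mask, frac)
            np.testing.assert_array_equal(got.grid, expected)

    def test_nesting_monotone(self, rng):
        mask = random_blob(rng)
        c25, c50, c75 = (extract_core(mask, f) for f in CORE_FRACTIONS)
        assert not (c25.grid & ~c50.grid).any()
        assert not (c50.grid & ~c75.grid).any()
        assert not (c75.grid & ~mask.grid).any()

    def test_degenerate_fraction_raises(self):
        grid = np.zeros((4, 4, 4), dtype=bool)
        grid[1, 1, 1] = True
        with pytest.raises(DegenerateRegionError):
            extract_core(VoxelMask(grid, (1, 1, 1)), 0.25)


class TestExtractPeriphery:
    def test_complement_partition_exact(self, ball8):
        for frac in CORE_FRACTIONS:
            peri = extract_periphery(ball8, frac)
            core = extract_core(ball8, 1.0 - frac)
            assert not (peri.grid & core.grid).any()
            np.testing.assert_array_equal(peri.grid | core.grid, ball8.grid)
            assert peri.count + core.count == ball8.count

    def test_rim_excludes_deep_voxels(self, ball10):
        peri = extract_periphery(ball10, 0.50)
        d = boundary_distance(ball10)
        threshold = d[extract_core(ball10, 0.50).grid].min()
        assert d[peri.grid].max() <= threshold

    def test_rim_is_hollow(self, ball10):
        peri = extract_periphery(ball10, 0.25)
        centroid = tuple(int(round(c)) for c in np.argwhere(ball10.grid).mean(axis=0))
        assert not peri.grid[centroid]


class TestSubregionSet:
    def test_seven_regions_with_expected_counts(self, ball10):
        regions = build_subregion_set(ball10)
        counts = regions.counts()
        assert len(counts) == 7
        n = ball10.count
        for f in CORE_FRACTIONS:
            assert abs(counts[f"core{int(f*100)}"] - f * n) <= 1
            assert counts[f"core{int(f*100)}"] + counts[f"periphery{int((1-f)*100)}"] == n

    def test_tiny_cube_flags_degenerate_core(self):
        grid = np.zeros((4, 4, 4), dtype=bool)
        grid[1:3, 1:3, 1:3] = True
        regions = build_subregion_set(VoxelMask(grid, (1, 1, 1)))
        assert "below_roi_minimum" in regions.flags.get("core25", [])

    def test_multi_component_mask_keeps_invariants(self, rng):
        grid = np.zeros((16, 16, 16), dtype=bool)
        grid[2:7, 2:7, 2:7] = True
        grid[10:14, 10:14, 10:14] = True
        regions = build_subregion_set(VoxelMask(grid, (1, 1, 1)))
        n = int(grid.sum())
        for f in CORE_FRACTIONS:
            core = regions.cores[f]
            peri = regions.peripheries[1.0 - f]
            np.testing.assert_array_equal(core.grid | peri.grid, grid)
            assert abs(core.count - f * n) <= 1
        assert "multi_component_parent" in regions.flags.get("core25", [])

    def test_rotation_robustness(self, ball10):
        core = extract_core(ball10, 0.50)
        rotated_mask = VoxelMask(np.rot90(ball10.grid, axes=(0, 1)), ball10.spacing_mm)
        core_rot = extract_core(rotated_mask, 0.50)
        back = VoxelMask(np.rot90(core_rot.grid, k=-1, axes=(0, 1)), ball10.spacing_mm)
        assert dice(core, back) >= 0.95


class TestDice:
    def test_identical_and_disjoint(self, ball8):
        assert dice(ball8, ball8) == 1.0
        empty = VoxelMask(np.zeros_like(ball8.grid), ball8.spacing_mm)
        assert dice(ball8, empty) == 0.0
        assert dice(empty, empty) == 1.0

    def test_inter_reader_agreement_value(self):
        # two 100-voxel masks overlapping on 93 voxels -> Dice 0.93
        a = np.zeros((5, 5, 10), dtype=bool)
        b = np.zeros((5, 5, 10), dtype=bool)
        a.ravel()[:100] = True
        b.ravel()[7:107] = True
        assert dice(VoxelMask(a, (1, 1, 1)), VoxelMask(b, (1, 1, 1))) == pytest.approx(0.93)

    def test_shape_mismatch_raises(self, ball8, ball10):
        with pytest.raises(AlignmentError):
            dice(ball8, ball10)


class TestSubregionOutput:
    def test_nifti_and_sidecar_round_trip(self, ball8, tmp_path):
        import json

        import nibabel as nib

        from subgrade.subregions import build_subregion_set, write_subregion_set

        regions = build_subregion_set(ball8)
        sidecar = write_subregion_set(regions, "S0001", tmp_path)
        stored = json.loads((tmp_path / "S0001_subregions.json").read_text())
        assert stored["voxel_counts"] == {k: int(v) for k, v in regions.counts().items()}
        core = nib.load(tmp_path / "S0001_core50.nii.gz")
        np.testing.assert_array_equal(
            np.asarray(core.dataobj) > 0, regions.cores[0.50].grid
        )
        assert sidecar["spacing_mm"] == [1.0, 1.0, 1.0]
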