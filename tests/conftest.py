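"""Shared fixtures: small geometric masks and images, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from subgrade.image import ImageVolume
from subgrade.subregions import VoxelMask


def make_ball(radius_vox: int, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> VoxelMask:
    """Digital ball of the given radius (in voxels) centred in a snug grid."""
    n = 2 * radius_vox + 1 + 2 * margin
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    grid = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    return VoxelMask(grid, spacing)


def random_blob(rng: np.random.Generator, n: int = 16, spacing=(1.0, 1.0, 1.0)) -> VoxelMask:
    """Random connected-ish blob: thresholded smoothed noise, non-empty."""
    from scipy import ndimage

    while True:
        noise = ndimage.gaussian_filter(rng.standard_normal((n, n, n)), sigma=2.0)
        grid = noise > np.percentile(noise, 75)
        mask = VoxelMask(grid, spacing)
        if mask.count >= 8 and mask.meets_roi_minimum():
            return mask


@pytest.fixture
def ball10() -> VoxelMask:
    return make_ball(10)


@pytest.fixture
def ball8() -> VoxelMask:
    return make_ball(8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240416)


@pytest.fixture
def noisy_image(ball10, rng) -> ImageVolume:
    grid = np.full(ball10.grid.shape, -50.0)
    grid[ball10.grid] = 80.0 + 25.0 * rng.standard_normal(ball10.count)
    return ImageVolume(grid, ball10.spacing_mm)
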