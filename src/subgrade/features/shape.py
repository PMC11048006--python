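"""3D shape features of a binary mask.

Volume and surface area come from a triangulated iso-surface of the mask
(marching cubes at level 0.5 on the zero-padded mask, honouring voxel
spacing); diameters are maximal vertex-pair distances (computed on convex
hulls, which carry the extremes); axis lengths derive from the
eigen-decomposition of the physical voxel-coordinate covariance.

Planar or linear regions are handled with defined limits (zero least-axis
length and flatness) rather than errors.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from ..subregions import EmptyMaskError, VoxelMask

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Compactness2",
    "SphericalDisproportion",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


_MAX_DIAMETER_POINTS = 3000


def _fibonacci_directions(n: int, dim: int) -> np.ndarray:
    if dim == 2:
        theta = np.linspace(0.0, np.pi, n, endpoint=False)  # antipodal pairs equivalent
        return np.column_stack([np.cos(theta), np.sin(theta)])
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([z, r * np.cos(phi), r * np.sin(phi)])


def _max_pair_distance(points: np.ndarray) -> float:
    """Largest pairwise distance.

    Small sets are done exactly; large sets (every vertex of a convex body
    sits on its own hull, so hull pruning does not help) are first reduced
    to the extremal points along a dense set of directions, which bounds
    the diameter to sub-voxel accuracy.
    """
    if len(points) < 2:
        return 0.0
    if len(points) > 600:
        if len(points) > _MAX_DIAMETER_POINTS:  # vertices sit within ~half a voxel
            stride = int(np.ceil(len(points) / _MAX_DIAMETER_POINTS))
            points = points[::stride]
        dirs = _fibonacci_directions(128 if points.shape[1] == 3 else 64, points.shape[1])
        proj = points @ dirs.T
        cand = np.unique(np.concatenate([proj.argmax(axis=0), proj.argmin(axis=0)]))
        points = points[cand]
    elif len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (flat) point sets: brute force below
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())


def shape_features(mask: VoxelMask) -> dict[str, float]:
    if mask.count == 0:
        raise EmptyMaskError("shape features require a non-empty mask")
    spacing = np.asarray(mask.spacing_mm)
    padded = np.pad(mask.grid, 3).astype(np.float64)
    # anti-aliased iso-surface: meshing the binary grid directly inflates the
    # area by ~9% through staircase facets; a one-voxel Gaussian smooths the
    # staircase. Thin (single-voxel) structures would vanish, so fall back.
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    surface_grid = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(
        surface_grid, level=0.5, spacing=tuple(spacing)
    )

    tri = verts[faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    mesh_volume = float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0))
    surface_area = float(np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum() / 2.0)

    voxel_volume = mask.count * float(np.prod(spacing))
    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
    compactness2 = 36.0 * np.pi * mesh_volume**2 / surface_area**3

    max3d = _max_pair_distance(verts)
    # in-plane diameters: maximal distance in each coordinate-pair projection
    max2d_slice = _max_pair_distance(verts[:, 1:3])  # row-column plane
    max2d_column = _max_pair_distance(verts[:, [0, 2]])
    max2d_row = _max_pair_distance(verts[:, [0, 1]])

    coords = np.argwhere(mask.grid) * spacing
    if len(coords) > 1:
        cov = np.cov(coords, rowvar=False, bias=False)
        eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": float(sphericity),
        "Compactness2": float(compactness2),
        "SphericalDisproportion": float(1.0 / sphericity) if sphericity > 0 else 0.0,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_column,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
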