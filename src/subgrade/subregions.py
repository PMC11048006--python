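"""Decomposition of a 3D tumour mask into volume-fraction cores and peripheries.

The tumour volume of interest (VOI) is split into seven analysis regions:
the full mask, three *cores* holding the deepest 25/50/75% of the tumour
volume, and three *peripheries* (hollow rims) holding the outermost
25/50/75%.  Depth is Euclidean distance to the nearest background voxel,
honouring anisotropic voxel spacing, so a periphery at fraction p is exactly
the set complement of the core at fraction 1-p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CORE_FRACTIONS = (0.25, 0.50, 0.75)

__all__ = [
    "VoxelMask",
    "SubregionSet",
    "boundary_distance",
    "extract_core",
    "extract_periphery",
    "build_subregion_set",
    "dice",
    "DegenerateRegionError",
    "AlignmentError",
    "EmptyMaskError",
]


class EmptyMaskError(ValueError):
    """Raised when an operation receives a mask with no foreground voxels."""


class DegenerateRegionError(ValueError):
    """Raised when a requested sub-region would contain no voxels."""


class AlignmentError(ValueError):
    """Raised when two volumes disagree in shape or voxel spacing."""


@dataclass(frozen=True)
class VoxelMask:
    """A 3D binary volume of interest with anisotropic voxel spacing.

    Parameters
    ----------
    grid
        Boolean 3D array; ``True`` marks tumour voxels.
    spacing_mm
        Voxel edge length along each axis, in millimetres.
    """

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        spacing = tuple(float(s) for s in self.spacing_mm)
        object.__setattr__(self, "spacing_mm", spacing)
        if grid.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got ndim={grid.ndim}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {spacing}")

    @property
    def count(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def extent(self) -> tuple[int, int, int]:
        """Foreground bounding-box size in voxels along each axis (0 if empty)."""
        if self.count == 0:
            return (0, 0, 0)
        idx = np.nonzero(self.grid)
        return tuple(int(ax.max() - ax.min() + 1) for ax in idx)

    def meets_roi_minimum(self, min_dim: int = 2) -> bool:
        """Whether the foreground spans at least ``min_dim`` voxels on every axis."""
        return all(e >= min_dim for e in self.extent())


def _check_same_grid(a: VoxelMask, b: VoxelMask) -> None:
    if a.grid.shape != b.grid.shape:
        raise AlignmentError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm):
        raise AlignmentError(f"spacing mismatch: {a.spacing_mm} vs {b.spacing_mm}")


def boundary_distance(mask: VoxelMask) -> np.ndarray:
    """Euclidean distance (mm) from each foreground voxel to the nearest background voxel.

    Background voxels map to 0.  Voxels on the grid edge are treated as
    adjacent to background (the volume is embedded in air), so an isolated
    foreground voxel at unit spacing has distance 1.
    """
    if mask.count == 0:
        raise EmptyMaskError("cannot compute distances on an empty mask")
    padded = np.pad(mask.grid, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=mask.spacing_mm)
    return np.ascontiguousarray(dist[1:-1, 1:-1, 1:-1])


def _deepest_voxels(mask: VoxelMask, n: int) -> np.ndarray:
    """Boolean grid holding the n deepest foreground voxels.

    Ties at the cut distance are resolved in lexicographic (z, y, x) voxel
    order, so the result is deterministic across runs and platforms.
    """
    dist = boundary_distance(mask)
    zz, yy, xx = np.nonzero(mask.grid)
    depth = dist[zz, yy, xx]
    # lexsort: last key is primary -> sort by (-depth, z, y, x)
    order = np.lexsort((xx, yy, zz, -depth))
    take = order[:n]
    out = np.zeros_like(mask.grid)
    out[zz[take], yy[take], xx[take]] = True
    return out


def extract_core(mask: VoxelMask, fraction: float) -> VoxelMask:
    """Return the core holding the given fraction of the tumour volume.

    The core is the ``round(fraction * |mask|)`` foreground voxels with the
    greatest boundary distance (the deepest voxels). ``fraction == 1.0``
    returns the mask unchanged.
    """
    if mask.count == 0:
        raise EmptyMaskError("cannot extract a core from an empty mask")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return mask
    n = int(round(fraction * mask.count))
    if n < 1:
        raise DegenerateRegionError(
            f"core fraction {fraction} of {mask.count} voxels is empty"
        )
    return VoxelMask(_deepest_voxels(mask, n), mask.spacing_mm)


def extract_periphery(mask: VoxelMask, fraction: float) -> VoxelMask:
    """Return the hollow rim holding the given fraction of the tumour volume.

    Defined by subtraction: ``periphery(p) = mask \\ core(1 - p)``, so core
    and periphery at complementary fractions partition the mask exactly.
    """
    if fraction not in (0.25, 0.50, 0.75):
        raise ValueError(f"periphery fraction must be 0.25/0.50/0.75, got {fraction}")
    inner = extract_core(mask, 1.0 - fraction)
    rim = mask.grid & ~inner.grid
    if not rim.any():
        raise DegenerateRegionError(f"periphery fraction {fraction} is empty")
    return VoxelMask(rim, mask.spacing_mm)


@dataclass
class SubregionSet:
    """The seven analysis regions of one tumour mask.

    ``flags`` records regions that fail the minimum ROI extent (2 voxels per
    axis) or whose core fell entirely into one connected component of a
    multi-component mask; flagged regions are kept, not dropped.
    """

    full: VoxelMask
    cores: dict[float, VoxelMask]
    peripheries: dict[float, VoxelMask]
    flags: dict[str, list[str]] = field(default_factory=dict)

    def region(self, kind: str, fraction: float = 1.0) -> VoxelMask:
        if kind == "full":
            return self.full
        if kind == "core":
            return self.cores[fraction]
        if kind == "periphery":
            return self.peripheries[fraction]
        raise KeyError(kind)

    def items(self):
        """Yield (region_name, VoxelMask) in canonical order."""
        yield "full", self.full
        for f in CORE_FRACTIONS:
            yield f"core{int(f * 100)}", self.cores[f]
        for f in CORE_FRACTIONS:
            yield f"periphery{int(f * 100)}", self.peripheries[f]

    def counts(self) -> dict[str, int]:
        return {name: m.count for name, m in self.items()}


def build_subregion_set(mask: VoxelMask, min_dim: int = 2) -> SubregionSet:
    """Decompose a mask into full + 3 cores + 3 peripheries.

    Degenerate regions raise :class:`DegenerateRegionError` with the region
    identity attached; regions that merely fail the ROI minimum extent are
    flagged in ``flags`` and retained.
    """
    if not mask.meets_roi_minimum(min_dim):
        raise DegenerateRegionError(
            f"full mask extent {mask.extent()} below ROI minimum {min_dim}"
        )
    flags: dict[str, list[str]] = {}
    cores: dict[float, VoxelMask] = {}
    peripheries: dict[float, VoxelMask] = {}
    n_components = ndimage.label(mask.grid)[1]
    for f in CORE_FRACTIONS:
        name = f"core{int(f * 100)}"
        try:
            core = extract_core(mask, f)
        except DegenerateRegionError as err:
            raise DegenerateRegionError(f"{name}: {err}") from err
        cores[f] = core
        region_flags = []
        if not core.meets_roi_minimum(min_dim):
            region_flags.append("below_roi_minimum")
        if n_components > 1:
            region_flags.append("multi_component_parent")
        if region_flags:
            flags[name] = region_flags
    for f in CORE_FRACTIONS:
        name = f"periphery{int(f * 100)}"
        rim = VoxelMask(mask.grid & ~cores[1.0 - f].grid, mask.spacing_mm)
        if rim.count == 0:
            raise DegenerateRegionError(f"{name}: empty rim")
        peripheries[f] = rim
        if not rim.meets_roi_minimum(min_dim):
            flags[name] = ["below_roi_minimum"]
    return SubregionSet(full=mask, cores=cores, peripheries=peripheries, flags=flags)


def write_subregion_set(regions: SubregionSet, subject_id: str, out_dir) -> dict:
    """Write each region as ``<subject>_<region>.nii.gz`` plus a JSON sidecar.

    The sidecar records per-region voxel counts and any flags, so degenerate
    regions are visible without reloading the masks.  Returns the sidecar
    content.
    """
    import json
    from pathlib import Path

    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(regions.full.spacing_mm) + [1.0])
    sidecar = {
        "subject_id": subject_id,
        "spacing_mm": list(regions.full.spacing_mm),
        "voxel_counts": regions.counts(),
        "flags": regions.flags,
    }
    for name, mask in regions.items():
        nib.save(
            nib.Nifti1Image(mask.grid.astype(np.uint8), affine),
            out_dir / f"{subject_id}_{name}.nii.gz",
        )
    (out_dir / f"{subject_id}_subregions.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    _check_same_grid(a, b)
    denom = a.count + b.count
    if denom == 0:
        return 1.0
    inter = int((a.grid & b.grid).sum())
    return 2.0 * inter / denom
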