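"""Scalar image volume container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image (Hounsfield-like units) with anisotropic voxel spacing."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        object.__setattr__(self, "grid", grid)
        spacing = tuple(float(s) for s in self.spacing_mm)
        object.__setattr__(self, "spacing_mm", spacing)
        if grid.ndim != 3:
            raise ValueError(f"image grid must be 3D, got ndim={grid.ndim}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {spacing}")
        if not np.isfinite(grid).all():
            raise ValueError("image contains non-finite values")
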