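"""Full radiomics battery for one (image, region-mask) pair.

The original image contributes 110 features (19 first-order + 24 GLCM +
16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM + 16 shape); every enabled filter
image contributes the 94 intensity/texture features again (shape is a
property of the mask alone and is computed once).  Names follow the
``<filter>_<class>_<Feature>`` convention, e.g. ``original_firstorder_Mean``
or ``wavelet-LLH_glcm_Contrast``, in a stable canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..image import ImageVolume
from ..subregions import DegenerateRegionError, VoxelMask
from .discretize import discretize
from .filters import DEFAULT_LOG_SIGMAS_MM, DEFAULT_WAVELET, expand_filter_names, filter_images
from .firstorder import first_order_features
from .shape import shape_features
from .texture import (
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

N_INTENSITY_TEXTURE = 19 + 24 + 16 + 16 + 14 + 5  # 94
N_SHAPE = 16
N_ORIGINAL = N_INTENSITY_TEXTURE + N_SHAPE  # 110

PAD_DISTANCE = 5


@dataclass(frozen=True)
class FeatureConfig:
    """Extractor settings: fixed bin width 20, no resampling, pad distance 5."""

    bin_width: float = 20.0
    filters: tuple[str, ...] = ()
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM
    wavelet: str = DEFAULT_WAVELET
    min_roi_dim: int = 2
    gldm_alpha: int = 0

    def expected_count(self) -> int:
        n_filter_images = len(expand_filter_names(self.filters, self.log_sigmas_mm))
        return N_ORIGINAL + n_filter_images * N_INTENSITY_TEXTURE


def _crop_with_pad(
    image: ImageVolume, mask: VoxelMask, pad: int = PAD_DISTANCE
) -> tuple[ImageVolume, VoxelMask]:
    """Restrict to the mask bounding box plus a pad of `pad` voxels (clipped)."""
    idx = np.nonzero(mask.grid)
    sl = tuple(
        slice(max(int(ax.min()) - pad, 0), min(int(ax.max()) + pad + 1, s))
        for ax, s in zip(idx, mask.grid.shape)
    )
    return (
        ImageVolume(np.ascontiguousarray(image.grid[sl]), image.spacing_mm),
        VoxelMask(np.ascontiguousarray(mask.grid[sl]), mask.spacing_mm),
    )


def _intensity_texture(
    image: ImageVolume, mask: VoxelMask, config: FeatureConfig
) -> dict[str, float]:
    disc = discretize(image, mask, config.bin_width)
    out: dict[str, float] = {}
    out.update({f"firstorder_{k}": v for k, v in first_order_features(image, mask, disc).items()})
    out.update({f"glcm_{k}": v for k, v in glcm_features(disc).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(disc).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(disc).items()})
    out.update({f"gldm_{k}": v for k, v in gldm_features(disc, config.gldm_alpha).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(disc).items()})
    return out


def extract_all(
    image: ImageVolume,
    mask: VoxelMask,
    config: FeatureConfig = FeatureConfig(),
    flags: list[str] | None = None,
) -> dict[str, float]:
    """Compute the complete feature vector for one region.

    Any non-finite sub-computation result is replaced by 0.0 and, when a
    ``flags`` list is supplied, the offending feature name is appended to it
    — features are never silently NaN.
    """
    if image.grid.shape != mask.grid.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.meets_roi_minimum(config.min_roi_dim):
        raise DegenerateRegionError(
            f"region extent {mask.extent()} below ROI minimum {config.min_roi_dim}"
        )
    image, mask = _crop_with_pad(image, mask)

    features: dict[str, float] = {}
    features.update(
        {f"original_shape_{k}": v for k, v in shape_features(mask).items()}
    )
    features.update(
        {f"original_{k}": v for k, v in _intensity_texture(image, mask, config).items()}
    )
    for fname, fimage in filter_images(
        image, mask, config.filters, config.wavelet, config.log_sigmas_mm
    ).items():
        features.update(
            {f"{fname}_{k}": v for k, v in _intensity_texture(fimage, mask, config).items()}
        )

    for name, value in features.items():
        if not np.isfinite(value):
            features[name] = 0.0
            if flags is not None:
                flags.append(name)
    return features
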