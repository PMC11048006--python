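"""First-order (intensity histogram) features.

19 features: the intensity statistics are computed on the raw masked
voxel values with population (n-denominator) moments; Entropy and
Uniformity use the fixed-bin-width discretised histogram.  Degenerate
(constant) regions return defined limits: variance 0, skewness 0,
kurtosis 0, entropy 0, uniformity 1.
"""

from __future__ import annotations

import numpy as np

from ..image import ImageVolume
from ..subregions import EmptyMaskError, VoxelMask
from .discretize import DiscretizedVolume

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    image: ImageVolume, mask: VoxelMask, disc: DiscretizedVolume
) -> dict[str, float]:
    x = image.grid[mask.grid].astype(np.float64)
    n = x.size
    if n < 2:
        raise EmptyMaskError("first-order features need at least 2 voxels")
    p = disc.histogram().astype(np.float64)
    p = p / p.sum()
    nz = p[p > 0]

    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    sd = np.sqrt(m2)
    if m2 > 0:
        skew = ((x - mean) ** 3).mean() / m2**1.5
        kurt = ((x - mean) ** 4).mean() / m2**2
    else:
        skew = 0.0
        kurt = 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = np.abs(robust - robust.mean()).mean() if robust.size else 0.0
    energy = float((x**2).sum())

    return {
        "Energy": energy,
        "TotalEnergy": float(np.prod(mask.spacing_mm)) * energy,
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "StandardDeviation": float(sd),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(m2),
        "Uniformity": float((nz**2).sum()),
    }
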