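"""Synthetic CT phantom cohorts for the sub-region grading pipeline.

Real arterial-phase CT cohorts of renal tumours cannot be redistributed, so
every downstream stage is exercised on seeded synthetic phantoms instead:
ellipsoidal tumours embedded in a uniform background, whose inner core and
outer shell carry class-dependent Gaussian-random-field textures, plus
additive acquisition noise.  Clinical covariate tables (age, sex, tumour
size and volume) are drawn from per-class normal distributions matching the
published cohort demographics.

The generator is a pure function of (config, seed): identical inputs yield
bit-identical volumes and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageVolume
from .subregions import AlignmentError, VoxelMask, extract_core

BACKGROUND_HU = -50.0
PAD_VOXELS = 5

__all__ = [
    "TextureSpec",
    "PhantomConfig",
    "ClassTextures",
    "ClinicalParams",
    "COHORT1_CLINICAL",
    "COHORT2_CLINICAL",
    "COHORT4_CLINICAL",
    "DEFAULT_CLASS_TEXTURES",
    "generate_phantom",
    "generate_cohort",
    "write_volume",
    "read_volume",
    "PhantomSizeError",
]


class PhantomSizeError(ValueError):
    """Raised when the ellipsoid (plus pad) does not fit inside the grid."""


@dataclass(frozen=True)
class TextureSpec:
    """First-order texture of one tumour compartment.

    mean_hu / sd_hu set the marginal intensity distribution;
    correlation_length_mm sets the spatial scale of the random field, i.e.
    how coarse the texture looks.
    """

    mean_hu: float
    sd_hu: float
    correlation_length_mm: float

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError(f"texture sd must be >= 0, got {self.sd_hu}")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation length must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """Full recipe for one synthetic tumour volume."""

    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    tumour_axes_mm: tuple[float, float, float]
    class_label: int
    core_texture: TextureSpec
    periphery_texture: TextureSpec
    noise_sd: float
    seed: int
    core_fraction: float = 0.50
    background_hu: float = BACKGROUND_HU

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 (low) or 1 (high)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.core_fraction < 1:
            raise ValueError("core_fraction must be in (0, 1)")
        max_sp = max(self.spacing_mm)
        if any(a <= 2 * max_sp for a in self.tumour_axes_mm):
            raise ValueError(
                f"semi-axes {self.tumour_axes_mm} must exceed 2*max(spacing)={2 * max_sp}"
            )
        for shape, sp, a in zip(self.grid_shape, self.spacing_mm, self.tumour_axes_mm):
            if a / sp + PAD_VOXELS > shape / 2:
                raise PhantomSizeError(
                    f"semi-axis {a} mm needs {a / sp:.1f}+{PAD_VOXELS} voxels per "
                    f"half-axis but grid allows {shape / 2:.1f}"
                )


# Per-class compartment textures.  The grade signal is a mean-intensity
# shift confined to the inner 50%-volume core (high-grade cores enhance
# more); second-order texture (sd, correlation length) and the peripheral
# shell are identical across grades, so the class signal lives only in the
# inner 50% of the tumour volume.  Low-grade tumours are homogeneous.
DEFAULT_CLASS_TEXTURES: dict[int, "ClassTextures"] = {}


@dataclass(frozen=True)
class ClassTextures:
    """Compartment textures for one grade class.

    ``periphery_mean_sd`` adds between-subject variation of the shell's mean
    enhancement (drawn once per subject, same distribution in every class),
    emulating patient-to-patient rim-enhancement differences without adding
    any class signal outside the core.
    """

    core: TextureSpec
    periphery: TextureSpec
    noise_sd: float = 10.0
    periphery_mean_sd: float = 0.0


DEFAULT_CLASS_TEXTURES[0] = ClassTextures(
    core=TextureSpec(70.0, 20.0, 5.0), periphery=TextureSpec(70.0, 20.0, 5.0)
)
DEFAULT_CLASS_TEXTURES[1] = ClassTextures(
    core=TextureSpec(90.0, 20.0, 5.0), periphery=TextureSpec(70.0, 20.0, 5.0)
)


def _ellipsoid_mask(config: PhantomConfig) -> np.ndarray:
    shape = config.grid_shape
    centre = [(s - 1) / 2.0 for s in shape]
    axes = config.tumour_axes_mm
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    q = np.zeros(shape, dtype=np.float64)
    for c, ctr, sp, a in zip(coords, centre, config.spacing_mm, axes):
        q += ((c - ctr) * sp / a) ** 2
    return q <= 1.0


def _random_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    tex: TextureSpec,
) -> np.ndarray:
    """Stationary Gaussian random field with the requested first-order moments.

    White noise is smoothed with a Gaussian kernel whose width equals the
    correlation length, then rescaled to unit variance before applying the
    target mean and sd, so mean/sd are controlled independently of the
    spatial scale.
    """
    if tex.sd_hu == 0:
        return np.full(shape, tex.mean_hu, dtype=np.float64)
    white = rng.standard_normal(shape)
    sigma_vox = [tex.correlation_length_mm / sp for sp in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pathological tiny grids
        return np.full(shape, tex.mean_hu, dtype=np.float64)
    return tex.mean_hu + tex.sd_hu * (smooth - smooth.mean()) / sd


def generate_phantom(config: PhantomConfig) -> tuple[ImageVolume, VoxelMask]:
    """Render one synthetic tumour volume and its binary mask.

    The mask is the discretised ellipsoid (a pure function of the geometry,
    independent of the seed).  The image is the background level outside the
    tumour, the periphery texture field on the outer shell, the core texture
    field on the inner ``core_fraction`` of the tumour volume, plus
    independent Gaussian acquisition noise everywhere.
    """
    grid = _ellipsoid_mask(config)
    mask = VoxelMask(grid, config.spacing_mm)
    if mask.count == 0:
        raise PhantomSizeError("ellipsoid discretised to an empty mask")
    core = extract_core(mask, config.core_fraction)

    rng = np.random.default_rng(config.seed)
    core_field = _random_field(rng, config.grid_shape, config.spacing_mm, config.core_texture)
    peri_field = _random_field(
        rng, config.grid_shape, config.spacing_mm, config.periphery_texture
    )
    image = np.full(config.grid_shape, config.background_hu, dtype=np.float64)
    image[mask.grid] = peri_field[mask.grid]
    image[core.grid] = core_field[core.grid]
    if config.noise_sd > 0:
        image += config.noise_sd * rng.standard_normal(config.grid_shape)
    return ImageVolume(image, config.spacing_mm), mask


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass(frozen=True)
class ClassStats:
    age: tuple[float, float]  # mean, sd (years)
    size_cm: tuple[float, float]  # mean, sd of max diameter
    male_fraction: float


@dataclass(frozen=True)
class ClinicalParams:
    """Per-class clinical covariate distributions for one cohort."""

    low: ClassStats
    high: ClassStats
    prevalence_high: float

    def stats(self, label: int) -> ClassStats:
        return self.high if label == 1 else self.low


# Published per-class demographics of the three source cohorts.
COHORT1_CLINICAL = ClinicalParams(
    low=ClassStats(age=(59.05, 12.28), size_cm=(4.32, 2.02), male_fraction=49 / 80),
    high=ClassStats(age=(64.0, 9.40), size_cm=(6.03, 3.23), male_fraction=74 / 107),
    prevalence_high=107 / 187,
)
COHORT2_CLINICAL = ClinicalParams(
    low=ClassStats(age=(57.17, 12.67), size_cm=(3.89, 2.16), male_fraction=77 / 127),
    high=ClassStats(age=(63.68, 11.14), size_cm=(6.81, 3.55), male_fraction=57 / 77),
    prevalence_high=77 / 204,
)
COHORT4_CLINICAL = ClinicalParams(
    low=ClassStats(age=(57.12, 10.25), size_cm=(3.31, 0.94), male_fraction=12 / 17),
    high=ClassStats(age=(62.09, 9.39), size_cm=(4.02, 2.25), male_fraction=8 / 11),
    prevalence_high=11 / 28,
)

AGE_BOUNDS = (18.0, 100.0)
# Physical bounds for the phantom geometry: below 2 cm the ellipsoid would
# violate the semi-axis > 2*spacing invariant at the default 3 mm voxels;
# above 10 cm (>1.2 sd beyond the high-grade mean) the volumes become
# needlessly large for analysis.
SIZE_BOUNDS_CM = (2.0, 10.0)
DEFAULT_SPACING_MM = (3.0, 3.0, 3.0)
ASPECT_LOG_SD = 0.10  # lognormal scatter of the two minor/major axis ratios
VOLUME_LOG_SD = 0.15  # residual lognormal scatter of volume around the ellipsoid value


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    while True:  # rejection sampling keeps the draw stream simple and exact
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    grade_label: int
    age_years: float
    sex: str
    tumour_size_cm: float
    tumour_volume_cm3: float

    def __post_init__(self) -> None:
        if self.tumour_size_cm <= 0 or self.tumour_volume_cm3 <= 0:
            raise ValueError("tumour size and volume must be positive")
        if not AGE_BOUNDS[0] <= self.age_years <= AGE_BOUNDS[1]:
            raise ValueError(f"age {self.age_years} outside {AGE_BOUNDS}")


def _grid_for_axes(
    axes_mm: tuple[float, float, float], spacing: tuple[float, float, float]
) -> tuple[int, int, int]:
    return tuple(
        int(2 * np.ceil(a / sp + PAD_VOXELS + 1)) for a, sp in zip(axes_mm, spacing)
    )


def generate_cohort(
    n: int,
    prevalence_high: float | None = None,
    clinical_params: ClinicalParams = COHORT1_CLINICAL,
    seed: int = 0,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    class_textures: dict[int, ClassTextures] = DEFAULT_CLASS_TEXTURES,
    core_fraction: float = 0.50,
) -> tuple[pd.DataFrame, list[PhantomConfig]]:
    """Draw a synthetic cohort: clinical table plus one phantom recipe per subject.

    Labels are Bernoulli(prevalence_high); age and tumour size come from the
    per-class normals truncated to physical bounds; tumour volume follows
    the ellipsoid relation V = 4/3*pi*a*b*c with lognormal scatter; the
    phantom semi-axes are size/2 along the major axis with mild random
    eccentricity on the other two.
    """
    if n < 4:
        raise ValueError(f"cohort size must be >= 4, got {n}")
    if prevalence_high is None:
        prevalence_high = clinical_params.prevalence_high
    if not 0 < prevalence_high < 1:
        raise ValueError(f"prevalence_high must be in (0, 1), got {prevalence_high}")

    rng = np.random.default_rng(seed)
    rows = []
    configs = []
    for i in range(n):
        label = int(rng.random() < prevalence_high)
        stats = clinical_params.stats(label)
        age = _truncated_normal(rng, *stats.age, *AGE_BOUNDS)
        size = _truncated_normal(rng, *stats.size_cm, *SIZE_BOUNDS_CM)
        sex = "male" if rng.random() < stats.male_fraction else "female"
        # semi-axes (mm): major = size/2, minors shrunk by lognormal ratios <= 1
        a_mm = size * 10.0 / 2.0
        ratios = np.exp(-np.abs(rng.normal(0.0, ASPECT_LOG_SD, size=2)))
        axes = (a_mm, float(a_mm * ratios[0]), float(a_mm * ratios[1]))
        min_axis = 2 * max(spacing_mm) + 1e-6
        axes = tuple(max(ax, min_axis) for ax in axes)
        volume_cm3 = (
            4.0 / 3.0 * np.pi * axes[0] * axes[1] * axes[2] / 1000.0
        ) * float(np.exp(rng.normal(0.0, VOLUME_LOG_SD)))
        tex = class_textures[label]
        periphery = tex.periphery
        if tex.periphery_mean_sd > 0:
            periphery = replace(
                periphery,
                mean_hu=periphery.mean_hu + rng.normal(0.0, tex.periphery_mean_sd),
            )
        subject_seed = int(rng.integers(0, 2**31 - 1))
        configs.append(
            PhantomConfig(
                grid_shape=_grid_for_axes(axes, spacing_mm),
                spacing_mm=spacing_mm,
                tumour_axes_mm=axes,
                class_label=label,
                core_texture=tex.core,
                periphery_texture=periphery,
                noise_sd=tex.noise_sd,
                seed=subject_seed,
                core_fraction=core_fraction,
            )
        )
        rows.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                grade_label=label,
                age_years=round(age, 2),
                sex=sex,
                tumour_size_cm=round(size, 3),
                tumour_volume_cm3=round(volume_cm3, 3),
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows])
    return table, configs


# ---------------------------------------------------------------------------
# NIfTI round-trip


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(image: ImageVolume, mask: VoxelMask, stem: str | Path) -> tuple[Path, Path]:
    """Write image and mask as a NIfTI pair ``<stem>_image.nii.gz`` / ``<stem>_mask.nii.gz``."""
    if image.grid.shape != mask.grid.shape:
        raise AlignmentError(
            f"image shape {image.grid.shape} != mask shape {mask.grid.shape}"
        )
    if not np.allclose(image.spacing_mm, mask.spacing_mm):
        raise AlignmentError(
            f"image spacing {image.spacing_mm} != mask spacing {mask.spacing_mm}"
        )
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img_path = stem.with_name(stem.name + "_image.nii.gz")
    mask_path = stem.with_name(stem.name + "_mask.nii.gz")
    nib.save(nib.Nifti1Image(image.grid.astype(np.float64), _affine(image.spacing_mm)), img_path)
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(mask.spacing_mm)), mask_path)
    return img_path, mask_path


def read_volume(stem: str | Path) -> tuple[ImageVolume, VoxelMask]:
    """Read back a volume pair written by :func:`write_volume`."""
    stem = Path(stem)
    img_nii = nib.load(stem.with_name(stem.name + "_image.nii.gz"))
    mask_nii = nib.load(stem.with_name(stem.name + "_mask.nii.gz"))
    img_sp = tuple(float(z) for z in img_nii.header.get_zooms()[:3])
    mask_sp = tuple(float(z) for z in mask_nii.header.get_zooms()[:3])
    if img_nii.shape != mask_nii.shape:
        raise AlignmentError(f"shape mismatch: {img_nii.shape} vs {mask_nii.shape}")
    if not np.allclose(img_sp, mask_sp):
        raise AlignmentError(f"spacing mismatch: {img_sp} vs {mask_sp}")
    image = ImageVolume(np.asarray(img_nii.dataobj, dtype=np.float64), img_sp)
    mask = VoxelMask(np.asarray(mask_nii.dataobj) > 0, mask_sp)
    return image, mask
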