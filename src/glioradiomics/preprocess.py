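"""Intensity normalization, two-point ADC mapping, outlier removal, resampling.

The CE-T1W channel is brought onto a comparable scale across subjects by
masked z-normalization (mean 0 / unit SD inside a brain mask). The ADC map
comes from the mono-exponential two-point decay ADC = ln(S0/Sb)/b; voxels
with non-positive signal are flagged invalid rather than silently zeroed,
and within-ROI outliers beyond ±3 SD of the mean are flagged the same way.
Volumes are resampled to isotropic voxels with tri-linear interpolation
(nearest-neighbour for masks, which stay binary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import TumorMask, VolumeImage


@dataclass
class ADCMap:
    """Apparent diffusion coefficient grid (mm^2/s) with an invalidity mask."""

    values: np.ndarray
    b_value: float = 1000.0
    invalid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.invalid_mask is None:
            self.invalid_mask = np.zeros(self.values.shape, dtype=bool)
        self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)
        if self.invalid_mask.shape != self.values.shape:
            raise ValueError("invalid_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.invalid_mask])):
            raise ValueError("valid ADC voxels must be finite")

    def to_volume(self) -> VolumeImage:
        """ADC as a VolumeImage with invalid voxels encoded as NaN."""
        vals = self.values.copy()
        vals[self.invalid_mask] = np.nan
        return VolumeImage(vals, self.voxel_size_mm, "ADC")


def normalize_intensity(img: VolumeImage, brain_mask: TumorMask) -> VolumeImage:
    """Masked z-normalization: within-mask mean 0, unit (sample) SD.

    Outside-mask voxels go through the same affine map, so relative contrast
    is preserved everywhere.
    """
    if not img.same_grid(brain_mask):
        raise ValueError("image and mask grids differ")
    n = brain_mask.voxel_count
    if n < 2:
        raise ValueError(f"brain mask has {n} voxel(s); need at least 2")
    inside = img.values[brain_mask.values]
    mu = inside.mean()
    sd = inside.std(ddof=1)
    if sd == 0:
        raise ValueError("constant image within mask: zero variance")
    return img.with_values((img.values - mu) / sd)


def compute_adc_map(b0: VolumeImage, b1000: VolumeImage, b: float = 1000.0) -> ADCMap:
    """Two-point decay estimate ADC = ln(S0/Sb)/b, invalid where signal <= 0."""
    if b <= 0:
        raise ValueError("b must be positive")
    if not b0.same_grid(b1000):
        raise ValueError("b0/b1000 grids differ")
    s0 = b0.values
    sb = b1000.values
    invalid = (s0 <= 0) | (sb <= 0)
    adc = np.zeros_like(s0)
    ok = ~invalid
    adc[ok] = np.log(s0[ok] / sb[ok]) / b
    return ADCMap(values=adc, b_value=b, invalid_mask=invalid, voxel_size_mm=b0.voxel_size_mm)


def clip_adc_outliers(adc: ADCMap, roi: TumorMask, n_sd: float = 3.0) -> ADCMap:
    """Flag ROI voxels beyond n_sd sample SDs of the single-pass ROI mean.

    Values are untouched; offending voxels join ``invalid_mask``.
    """
    if roi.voxel_count == 0:
        raise ValueError("empty ROI")
    valid_roi = roi.values & ~adc.invalid_mask
    vals = adc.values[valid_roi]
    if vals.size == 0:
        raise ValueError("all ROI voxels are invalid")
    mu = vals.mean()
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    invalid = adc.invalid_mask.copy()
    if sd > 0:
        invalid |= valid_roi & (np.abs(adc.values - mu) > n_sd * sd)
    return ADCMap(values=adc.values.copy(), b_value=adc.b_value, invalid_mask=invalid, voxel_size_mm=adc.voxel_size_mm)


def _resample(values: np.ndarray, spacing: tuple[float, float, float], target_mm: float, order: int) -> np.ndarray:
    out_shape = tuple(int(np.ceil(n * s / target_mm)) for n, s in zip(values.shape, spacing))
    coords = np.meshgrid(
        *[np.arange(m) * target_mm / s for m, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    return ndimage.map_coordinates(values, np.stack(coords), order=order, mode="nearest")


def resample_isotropic(img: VolumeImage, target_mm: float = 1.0) -> VolumeImage:
    """Tri-linear resampling onto a target isotropic voxel size."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    vals = _resample(img.values, img.voxel_size_mm, target_mm, order=1)
    return VolumeImage(vals, (target_mm,) * 3, img.modality)


def resample_mask_isotropic(mask: TumorMask, target_mm: float = 1.0) -> TumorMask:
    """Nearest-neighbour resampling so masks stay binary."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    vals = _resample(mask.values.astype(np.float64), mask.voxel_size_mm, target_mm, order=0)
    return TumorMask(vals > 0.5, (target_mm,) * 3)


def register(moving: VolumeImage, fixed: VolumeImage) -> VolumeImage:
    """Co-registration hook.

    Phantom subjects are generated on a shared grid, so this is the identity;
    the hook keeps the pipeline's stage sequence explicit and gives real-data
    users a single place to plug an affine registration in.
    """
    if not moving.same_grid(fixed):
        raise ValueError("identity registration requires matching grids")
    return moving
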