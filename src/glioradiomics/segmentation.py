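"""Semi-automatic tumor ROI: intensity band + 3-D region growing (26-conn).

Mirrors the interactive threshold/region-growing procedure of clinical
toolkits; manual editing is replaced by accepting an externally supplied
mask override in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import TumorMask, VolumeImage

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedPoint:
    i: int
    j: int
    k: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


def region_grow(img: VolumeImage, seed: SeedPoint | tuple[int, int, int], low: float, high: float = np.inf) -> TumorMask:
    """Maximal 26-connected set containing the seed with intensities in [low, high]."""
    seed_t = seed.as_tuple() if isinstance(seed, SeedPoint) else tuple(seed)
    if any(not (0 <= s < n) for s, n in zip(seed_t, img.shape)):
        raise ValueError(f"seed {seed_t} outside grid {img.shape}")
    seed_val = img.values[seed_t]
    if not (low <= seed_val <= high):
        raise ValueError(f"seed intensity {seed_val} outside threshold band [{low}, {high}]")
    band = (img.values >= low) & (img.values <= high)
    labels, _ = ndimage.label(band, structure=_STRUCT_26)
    return TumorMask(labels == labels[seed_t], img.voxel_size_mm)


def largest_component(mask: TumorMask) -> TumorMask:
    """Largest 26-connected component; ties go to the lexicographically
    smallest member voxel."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    labels, n = ndimage.label(mask.values, structure=_STRUCT_26)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        # smallest flat index in C order == lexicographically smallest (i,j,k)
        flat = labels.ravel()
        winner = min(candidates, key=lambda c: int(np.flatnonzero(flat == c)[0]))
    return TumorMask(labels == winner, mask.voxel_size_mm)


def mask_stats(mask: TumorMask, img: VolumeImage) -> dict[str, float]:
    """Volume and first-order summary of the masked intensities."""
    if not mask.same_grid(img):
        raise ValueError("mask/image grids differ")
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    vals = img.values[mask.values]
    return {
        "volume_mm3": mask.voxel_count * mask.voxel_volume_mm3,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "min": float(vals.min()),
        "max": float(vals.max()),
    }
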