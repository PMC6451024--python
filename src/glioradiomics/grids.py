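"""Core volumetric containers shared by every stage of the pipeline.

A :class:`VolumeImage` is a 3-D scalar grid with physical voxel spacing and a
modality tag; a :class:`TumorMask` is a binary grid on the same lattice. All
imaging stages (phantom synthesis, preprocessing, segmentation, radiomics)
consume and produce these two types, so their invariants are checked eagerly
at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Modalities recognised by the pipeline.
MODALITIES = ("CE-T1W", "DW-b0", "DW-b1000", "ADC", "derived")


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


@dataclass
class VolumeImage:
    """A 3-D scalar image with voxel spacing (mm) and a modality tag."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "derived"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.values.ndim}")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel spacing must be 3 strictly positive values, got {self.voxel_size_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "VolumeImage":
        """Copy of this image with new voxel data on the same grid."""
        return VolumeImage(
            values=np.asarray(values, dtype=np.float64),
            voxel_size_mm=self.voxel_size_mm,
            modality=modality or self.modality,
            affine=self.affine.copy(),
        )

    def same_grid(self, other: "VolumeImage | TumorMask") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size_mm, other.voxel_size_mm)


@dataclass
class TumorMask:
    """Binary ROI on the same lattice as its source image."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={vals.ndim}")
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary")
            vals = vals.astype(bool)
        self.values = vals
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_grid(self, other: "VolumeImage | TumorMask") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
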