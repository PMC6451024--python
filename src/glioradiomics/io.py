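"""NIfTI round-trips for volumes and masks (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import TumorMask, VolumeImage


def save_volume(img: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(np.asarray(img.values, dtype=np.float32), img.affine)
    nii.header.set_zooms(img.voxel_size_mm)
    nib.save(nii, str(path))
    return path


def load_volume(path: str | Path, modality: str = "derived") -> VolumeImage:
    nii = nib.load(str(path))
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return VolumeImage(
        values=np.asarray(nii.dataobj, dtype=np.float64),
        voxel_size_mm=zooms,
        modality=modality,
        affine=np.asarray(nii.affine),
    )


def save_mask(mask: TumorMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine)
    nii.header.set_zooms(mask.voxel_size_mm)
    nib.save(nii, str(path))
    return path


def load_mask(path: str | Path) -> TumorMask:
    nii = nib.load(str(path))
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return TumorMask(values=np.asarray(nii.dataobj) > 0, voxel_size_mm=zooms, affine=np.asarray(nii.affine))
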