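"""Seeded phantom cohorts emulating the two tumor classes and a site shift.

Each synthetic subject carries a contrast-enhanced T1-weighted volume, a
diffusion-weighted pair (b = 0 and b = 1000 s/mm^2) and an exact tumor mask.
The two diagnostic entities are separated by the qualitative contrast the
classifiers must learn from real data:

* **glioblastoma** — ring enhancement on CE-T1W (bright rim, darker core),
  high within-tumor texture heterogeneity, ADC around 1.0e-3 mm^2/s;
* **PCNSL** — homogeneous enhancement, low heterogeneity, hypercellular
  tissue with ADC around 0.7e-3 mm^2/s.

Texture is synthesised as Gaussian random fields with a class-specific
correlation length, so co-occurrence and run-length statistics genuinely
differ between classes. A :class:`ProtocolShift` emulates an external site:
thick-slice acquisition (resampled back to the native grid), extra blur,
noise, intensity scaling and a nuisance drift, applied to images only —
never to masks or labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as gio
from .grids import TumorMask, VolumeImage

GBM = "glioblastoma"
PCNSL = "PCNSL"
B_VALUE = 1000.0  # s/mm^2

#: background ("normal brain") appearance shared by both classes
_BG_T1 = 40.0
_BG_ADC = 0.8e-3  # mm^2/s
_BG_S0 = 500.0
_ADC_FLOOR = 1e-5  # mm^2/s; keeps generated ADC strictly positive


@dataclass
class ClassAppearance:
    """Appearance parameters for one tumor class on the phantom."""

    rim_intensity: float = 160.0
    core_intensity: float = 60.0
    enh_intensity: float = 120.0
    texture_corr_length: float = 4.0  # voxels
    adc_mean: float = 1.0e-3  # mm^2/s
    heterogeneity_sd: float = 25.0
    ring: bool = True  # rim/core enhancement pattern vs homogeneous


def gbm_defaults() -> ClassAppearance:
    return ClassAppearance(
        rim_intensity=160.0,
        core_intensity=60.0,
        enh_intensity=120.0,
        texture_corr_length=4.0,
        adc_mean=1.0e-3,
        heterogeneity_sd=25.0,
        ring=True,
    )


def pcnsl_defaults() -> ClassAppearance:
    return ClassAppearance(
        rim_intensity=120.0,
        core_intensity=120.0,
        enh_intensity=120.0,
        texture_corr_length=1.5,
        adc_mean=0.7e-3,
        heterogeneity_sd=8.0,
        ring=False,
    )


@dataclass
class PhantomSpec:
    """Everything needed to synthesise one subject deterministically."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)
    class_label: Literal["glioblastoma", "PCNSL"] = GBM
    gbm_params: ClassAppearance = field(default_factory=gbm_defaults)
    pcnsl_params: ClassAppearance = field(default_factory=pcnsl_defaults)
    noise_sd: float = 4.0
    atypical_fraction: float = 0.0  # reserved knob; no quantitative reference exists
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range must satisfy 0 < lo <= hi")
        margin = min(self.grid_shape) / 2.0 - 2.0
        if hi > margin:
            raise ValueError(
                f"tumor radius up to {hi} voxels cannot fit a {self.grid_shape} grid "
                f"with a 2-voxel margin (max {margin:.1f})"
            )
        if self.class_label not in (GBM, PCNSL):
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def params(self) -> ClassAppearance:
        return self.gbm_params if self.class_label == GBM else self.pcnsl_params


@dataclass
class ProtocolShift:
    """Acquisition differences of an external site, applied to images only."""

    intensity_scale: float = 1.0
    extra_noise_sd: float = 0.0
    blur_fwhm_mm: float = 0.0
    slice_thickness_mm: float = 1.0  # native; external DWI protocols run 3-5 mm
    te_tr_jitter: float = 0.0

    def validate(self, native_spacing_mm: float) -> None:
        if self.slice_thickness_mm < native_spacing_mm:
            raise ValueError("slice_thickness_mm must be >= native spacing")

    def is_identity(self, native_spacing_mm: float) -> bool:
        return (
            self.intensity_scale == 1.0
            and self.extra_noise_sd == 0.0
            and self.blur_fwhm_mm == 0.0
            and self.slice_thickness_mm == native_spacing_mm
            and self.te_tr_jitter == 0.0
        )


def external_site_shift() -> ProtocolShift:
    """Default external-site protocol: 4 mm slices, extra noise/blur, gain drift."""
    return ProtocolShift(
        intensity_scale=1.08,
        extra_noise_sd=6.0,
        blur_fwhm_mm=1.5,
        slice_thickness_mm=4.0,
        te_tr_jitter=5.0,
    )


@dataclass
class SubjectRecord:
    subject_id: str
    class_label: str
    ce_t1w: VolumeImage
    dw_b0: VolumeImage
    dw_b1000: VolumeImage
    mask_truth: TumorMask
    adc_true: VolumeImage | None = None
    seed_point: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        for vol in (self.dw_b0, self.dw_b1000):
            if not self.ce_t1w.same_grid(vol):
                raise ValueError("all volumes must share grid and spacing")
        if not self.ce_t1w.same_grid(self.mask_truth):
            raise ValueError("mask must share the image grid")
        if self.mask_truth.voxel_count == 0:
            raise ValueError("mask_truth is empty")
        if not self.mask_truth.values[self.seed_point]:
            raise ValueError("seed_point must lie inside mask_truth")


def _grf(rng: np.random.Generator, shape: tuple[int, int, int], corr_length: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length.

    Spectral synthesis via Gaussian smoothing of white noise; the field is
    renormalised to zero mean / unit SD so class parameters scale it directly.
    """
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma=corr_length, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _ellipsoid(
    rng: np.random.Generator, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Tumor support: perturbed ellipsoid level set and its normalized radius."""
    shape = np.array(spec.grid_shape)
    lo, hi = spec.tumor_radius_range
    semi = rng.uniform(lo, hi, size=3)
    # keep the ellipsoid >= 2 voxels from every face
    semi = np.minimum(semi, shape / 2.0 - 2.0)
    center = shape / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    rho2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    rho = np.sqrt(rho2)
    # smooth boundary perturbation keeps the mask a single blob but non-spherical
    bump = 0.12 * _grf(rng, spec.grid_shape, corr_length=6.0)
    level = rho + bump
    mask = level <= 1.0
    seed_point = tuple(int(round(c)) for c in center)
    if not mask[seed_point]:  # perturbation pushed the surface past the centre
        mask[seed_point] = True
    return mask, np.clip(level, 0.0, None), seed_point


def generate_subject(spec: PhantomSpec, subject_id: str = "S000") -> SubjectRecord:
    """Synthesise one subject; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    mask, rho, seed_point = _ellipsoid(rng, spec)

    texture = _grf(rng, spec.grid_shape, p.texture_corr_length)
    bg_field = _grf(rng, spec.grid_shape, 8.0)

    ce = np.full(spec.grid_shape, _BG_T1) + 3.0 * bg_field
    if p.ring:
        # normalized ellipsoid radius: rim for rho in (0.7, 1], darker core inside
        rim = mask & (rho > 0.7)
        core = mask & ~rim
        ce[rim] = p.rim_intensity
        ce[core] = p.core_intensity
    else:
        ce[mask] = p.enh_intensity
    ce[mask] += p.heterogeneity_sd * texture[mask]

    adc = np.full(spec.grid_shape, _BG_ADC) + 0.03e-3 * bg_field
    adc_texture = _grf(rng, spec.grid_shape, p.texture_corr_length)
    adc[mask] = p.adc_mean + 0.08 * p.adc_mean * adc_texture[mask]
    adc = np.clip(adc, _ADC_FLOOR, None)

    s0 = np.full(spec.grid_shape, _BG_S0) + 20.0 * _grf(rng, spec.grid_shape, 3.0)
    if spec.noise_sd > 0:
        ce = ce + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        s0 = s0 + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
    s0 = np.clip(s0, 1.0, None)
    # two-point relation holds exactly by construction (see methods note)
    s1000 = s0 * np.exp(-B_VALUE * adc)

    vs = spec.voxel_size_mm
    return SubjectRecord(
        subject_id=subject_id,
        class_label=spec.class_label,
        ce_t1w=VolumeImage(ce, vs, "CE-T1W"),
        dw_b0=VolumeImage(s0, vs, "DW-b0"),
        dw_b1000=VolumeImage(s1000, vs, "DW-b1000"),
        mask_truth=TumorMask(mask, vs),
        adc_true=VolumeImage(adc, vs, "ADC"),
        seed_point=seed_point,
    )


def _subject_seed(cohort_seed: int, index: int) -> int:
    """Stable per-subject stream: hash of (cohort seed, subject index)."""
    ss = np.random.SeedSequence(entropy=int(cohort_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_gbm: int,
    n_pcnsl: int,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    id_prefix: str = "S",
) -> list[SubjectRecord]:
    """Seeded cohort: n_gbm glioblastoma subjects followed by n_pcnsl PCNSL."""
    if n_gbm < 1 or n_pcnsl < 1:
        raise ValueError("need at least one subject per class")
    template = spec_template or PhantomSpec()
    subjects: list[SubjectRecord] = []
    labels = [GBM] * n_gbm + [PCNSL] * n_pcnsl
    for i, label in enumerate(labels):
        spec = replace(template, class_label=label, seed=_subject_seed(seed, i))
        subjects.append(generate_subject(spec, subject_id=f"{id_prefix}{i:03d}"))
    return subjects


def _thick_slice(values: np.ndarray, spacing_mm: float, thickness_mm: float) -> np.ndarray:
    """Acquire at coarse z-resolution, then linearly upsample back to native."""
    nz = values.shape[2]
    factor = thickness_mm / spacing_mm
    n_thick = max(1, int(np.ceil(nz / factor)))
    # average native slices into each thick slab
    centers = (np.arange(n_thick) + 0.5) * factor - 0.5
    edges = np.clip(np.round((np.arange(n_thick + 1)) * factor).astype(int), 0, nz)
    thick = np.stack(
        [values[:, :, edges[i] : max(edges[i] + 1, edges[i + 1])].mean(axis=2) for i in range(n_thick)],
        axis=2,
    )
    # linear interpolation back onto the native slice positions
    z_native = np.arange(nz, dtype=float)
    out = np.empty_like(values)
    idx = np.interp(z_native, centers, np.arange(n_thick, dtype=float))
    lo = np.clip(np.floor(idx).astype(int), 0, n_thick - 1)
    hi = np.clip(lo + 1, 0, n_thick - 1)
    w = idx - lo
    out[:] = thick[:, :, lo] * (1 - w) + thick[:, :, hi] * w
    return out


def apply_protocol_shift(subject: SubjectRecord, shift: ProtocolShift, seed: int = 0) -> SubjectRecord:
    """Re-acquire a subject under a different protocol (images only).

    The identity shift returns bit-identical volumes. Otherwise, per image:
    thick-slice resampling (z), Gaussian blur, global intensity scale, a
    subject-level drift offset (TE/TR nuisance), then additive noise.
    """
    native = subject.ce_t1w.voxel_size_mm[2]
    shift.validate(native)
    if shift.is_identity(native):
        return subject

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(97,)))
    drift = rng.normal(0.0, shift.te_tr_jitter) if shift.te_tr_jitter > 0 else 0.0

    def transform(img: VolumeImage) -> VolumeImage:
        vals = img.values
        if shift.slice_thickness_mm > native:
            vals = _thick_slice(vals, native, shift.slice_thickness_mm)
        if shift.blur_fwhm_mm > 0:
            sigma = shift.blur_fwhm_mm / 2.3548200450309493  # FWHM -> SD
            vals = ndimage.gaussian_filter(vals, sigma=[sigma / s for s in img.voxel_size_mm])
        if shift.intensity_scale != 1.0:
            vals = vals * shift.intensity_scale
        if drift:
            vals = vals + drift
        if shift.extra_noise_sd > 0:
            vals = vals + rng.normal(0.0, shift.extra_noise_sd, vals.shape)
        return img.with_values(vals)

    return SubjectRecord(
        subject_id=subject.subject_id,
        class_label=subject.class_label,
        ce_t1w=transform(subject.ce_t1w),
        dw_b0=transform(subject.dw_b0),
        dw_b1000=transform(subject.dw_b1000),
        mask_truth=subject.mask_truth,
        adc_true=subject.adc_true,
        seed_point=subject.seed_point,
    )


def save_cohort(subjects: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write per-subject NIfTI files plus a cohort manifest CSV."""
    out_dir = Path(out_dir)
    rows = []
    for s in subjects:
        sdir = out_dir / s.subject_id
        gio.save_volume(s.ce_t1w, sdir / "ce_t1w.nii.gz")
        gio.save_volume(s.dw_b0, sdir / "dw_b0.nii.gz")
        gio.save_volume(s.dw_b1000, sdir / "dw_b1000.nii.gz")
        gio.save_mask(s.mask_truth, sdir / "mask.nii.gz")
        rows.append(
            {
                "subject_id": s.subject_id,
                "label": s.class_label,
                "seed_point": "{}:{}:{}".format(*s.seed_point),
                "ce_t1w": str(sdir / "ce_t1w.nii.gz"),
                "dw_b0": str(sdir / "dw_b0.nii.gz"),
                "dw_b1000": str(sdir / "dw_b1000.nii.gz"),
                "mask": str(sdir / "mask.nii.gz"),
            }
        )
    manifest = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_csv: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(manifest_csv)
    subjects = []
    for _, row in df.iterrows():
        seed_point = tuple(int(x) for x in str(row["seed_point"]).split(":"))
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                class_label=str(row["label"]),
                ce_t1w=gio.load_volume(row["ce_t1w"], "CE-T1W"),
                dw_b0=gio.load_volume(row["dw_b0"], "DW-b0"),
                dw_b1000=gio.load_volume(row["dw_b1000"], "DW-b1000"),
                mask_truth=gio.load_mask(row["mask"]),
                seed_point=seed_point,  # type: ignore[arg-type]
            )
        )
    return subjects
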