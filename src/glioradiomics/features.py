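"""The 936-feature extraction engine and the cross-subject z-transform.

Per channel (CE-T1W or ADC) and tumor mask, the engine computes 104 features
(17 first-order + 22 GLCM x 3 distances + 21 GLRLM) on the original volume
and on each of the 8 Haar sub-bands, in the fixed manifest order — 936
values. Texture descriptors are averaged over the 13 unique 3-D directions;
sub-band masks are the truth mask picked on the decimated lattice. If a
(sub-band) mask is empty or admits no voxel pair at some displacement the
affected features are 0 and a warning is emitted, so the vector length is
always exactly 936.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .firstorder import first_order_features
from .grids import TumorMask, VolumeImage
from .manifest import DEFAULT_MANIFEST, FeatureManifest
from .texture import (
    GrayLevelQuantization,
    compute_glcm,
    compute_glrlm,
    glcm_directions,
    glcm_features,
    glrlm_features,
    normalize_glcm,
    quantize,
)
from .wavelets import decimate_mask, wavelet_decompose

_DIRECTIONS = glcm_directions()


def _bbox_crop(values: np.ndarray, mask: np.ndarray, margin: int = 3):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def _source_features(
    values: np.ndarray,
    mask: np.ndarray,
    manifest: FeatureManifest,
    q: GrayLevelQuantization,
    source: str,
) -> list[float]:
    """104 features for one source volume, in manifest order."""
    out: list[float] = []
    if not mask.any():
        warnings.warn(f"empty mask on source {source}; its features are 0")
        n = len(manifest.first_order) + len(manifest.glcm) * len(manifest.distances) + len(manifest.glrlm)
        return [0.0] * n

    values, mask = _bbox_crop(values, mask)
    fo = first_order_features(values, mask, q)
    out.extend(fo[name] for name in manifest.first_order)

    levels = quantize(values, mask, q)
    n_levels = q.n_levels
    for d in manifest.distances:
        acc = np.zeros(len(manifest.glcm))
        n_ok = 0
        for direction in _DIRECTIONS:
            mat = compute_glcm(levels, mask, direction, distance=d, n_levels=n_levels)
            if mat.sum() == 0:
                continue
            f = glcm_features(normalize_glcm(mat))
            acc += np.array([f[name] for name in manifest.glcm])
            n_ok += 1
        if n_ok == 0:
            warnings.warn(f"no voxel pair at distance {d} on source {source}; GLCM features are 0")
            out.extend([0.0] * len(manifest.glcm))
        else:
            out.extend(acc / n_ok)

    n_vox = int(mask.sum())
    acc = np.zeros(len(manifest.glrlm))
    for direction in _DIRECTIONS:
        r = compute_glrlm(levels, mask, direction, n_levels=n_levels)
        f = glrlm_features(r, n_vox)
        acc += np.array([f[name] for name in manifest.glrlm])
    out.extend(acc / len(_DIRECTIONS))
    return out


def extract_all_features(
    img: VolumeImage,
    mask: TumorMask,
    manifest: FeatureManifest = DEFAULT_MANIFEST,
    q: GrayLevelQuantization = GrayLevelQuantization(),
) -> pd.Series:
    """The full 936-entry feature vector for one channel of one subject."""
    if not img.same_grid(mask):
        raise ValueError("image and mask grids differ")
    if mask.voxel_count == 0:
        raise ValueError("empty tumor mask")
    vals: list[float] = []
    vals.extend(_source_features(img.values, mask.values, manifest, q, "original"))
    bands = wavelet_decompose(img.values)
    for band_name in manifest.sources[1:]:
        band = bands[band_name]
        band_mask = decimate_mask(mask.values, band.shape)
        vals.extend(_source_features(band, band_mask, manifest, q, band_name))
    assert len(vals) == len(manifest)
    return pd.Series(vals, index=list(manifest.names), dtype=np.float64)


def build_feature_table(
    records: list[tuple[str, VolumeImage, TumorMask]],
    manifest: FeatureManifest = DEFAULT_MANIFEST,
) -> pd.DataFrame:
    """Rows = subjects, columns = manifest order."""
    rows = {sid: extract_all_features(img, mask, manifest) for sid, img, mask in records}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(manifest.names))


class FeatureScaler:
    """Per-feature (x - mean_fit) / SD_fit, fitted on training rows only."""

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, table: pd.DataFrame) -> "FeatureScaler":
        if len(table) < 2:
            raise ValueError("need at least 2 fit rows")
        self.mean_ = table.mean(axis=0)
        sd = table.std(axis=0, ddof=1)
        n_const = int((sd == 0).sum())
        if n_const:
            warnings.warn(f"{n_const} constant feature(s) in fit rows; transformed to 0")
        self.sd_ = sd.replace(0.0, np.nan)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        z = (table - self.mean_) / self.sd_
        return z.fillna(0.0)


def z_transform_features(
    table: pd.DataFrame, fit_rows: list[str] | pd.Index | None = None
) -> tuple[pd.DataFrame, FeatureScaler]:
    """Standardize a subjects x features table using the fit rows' statistics.

    Returns the transformed full table and the fitted scaler (to apply to
    validation cohorts).
    """
    fit = table if fit_rows is None else table.loc[fit_rows]
    scaler = FeatureScaler().fit(fit)
    return scaler.transform(table), scaler
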