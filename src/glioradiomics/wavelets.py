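"""Single-level 3-D discrete wavelet decomposition into 8 sub-bands.

Orthonormal Haar filters are applied separably along each axis with a
low-pass (L) or high-pass (H) branch, giving the LLL..HHH sub-band volumes;
the k-th letter of a band key is the filter applied along axis k.
Periodization boundary handling keeps the transform orthonormal on dyadic
grids (coefficient energy equals input energy) and remains well defined for
odd dimensions.
"""

from __future__ import annotations

import numpy as np
import pywt

from .manifest import WAVELET_BAND_NAMES

_WAVELET = "haar"
_MODE = "periodization"


def wavelet_decompose(values: np.ndarray, wavelet: str = _WAVELET) -> dict[str, np.ndarray]:
    """8 sub-band volumes keyed LLL..HHH (letter k = filter along axis k)."""
    if values.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if any(n < 2 for n in values.shape):
        raise ValueError("each axis needs at least 2 voxels")
    coeffs = pywt.dwtn(values, wavelet, mode=_MODE)
    bands: dict[str, np.ndarray] = {}
    for key, arr in coeffs.items():
        # pywt keys use 'a' (approximation = low-pass) / 'd' (detail = high-pass)
        name = key.replace("a", "L").replace("d", "H")
        bands[name] = np.asarray(arr, dtype=np.float64)
    assert set(bands) == set(WAVELET_BAND_NAMES)
    return bands


def decimate_mask(mask: np.ndarray, band_shape: tuple[int, ...]) -> np.ndarray:
    """Mask on the decimated lattice: nearest-neighbour pick of every 2nd voxel."""
    sub = mask[::2, ::2, ::2]
    # periodization can pad odd axes by one coefficient; crop/pad to match
    out = np.zeros(band_shape, dtype=bool)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(sub.shape, band_shape))
    out[sl] = sub[sl]
    return out
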