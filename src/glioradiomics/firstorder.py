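"""First-order (histogram) statistics of the masked intensities.

17 descriptors: the 9 classic histogram statistics (range, energy, entropy,
kurtosis, maximum, mean, median, uniformity, variance) plus minimum,
skewness, standard deviation, RMS, mean absolute deviation, the 10th/90th
percentiles and the interquartile range. Entropy and uniformity are computed
on the same equal-width gray-level bins used by the texture matrices;
energy is the sum of squared intensities. Variance/SD use the sample (n-1)
convention; kurtosis is Pearson (normal -> 3).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .texture import GrayLevelQuantization, quantize


def first_order_features(
    values: np.ndarray, mask: np.ndarray, q: GrayLevelQuantization = GrayLevelQuantization()
) -> dict[str, float]:
    if not mask.any():
        raise ValueError("empty mask")
    x = values[mask].astype(np.float64)
    n = x.size
    levels = quantize(values, mask, q)[mask]
    counts = np.bincount(levels, minlength=q.n_levels + 1)[1:]
    p = counts / n
    pnz = p[p > 0]
    mean = float(x.mean())
    var = float(x.var(ddof=1)) if n > 1 else 0.0
    sd = float(np.sqrt(var))
    if sd > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True, fisher=False))
    else:
        skew, kurt = 0.0, 0.0
    return {
        "range": float(x.max() - x.min()),
        "energy": float((x**2).sum()),
        "entropy": float(-(pnz * np.log2(pnz)).sum()),
        "kurtosis": kurt,
        "maximum": float(x.max()),
        "mean": mean,
        "median": float(np.median(x)),
        "uniformity": float((p**2).sum()),
        "variance": var,
        "minimum": float(x.min()),
        "skewness": skew,
        "standard_deviation": sd,
        "root_mean_square": float(np.sqrt((x**2).mean())),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "percentile_10": float(np.percentile(x, 10)),
        "percentile_90": float(np.percentile(x, 90)),
        "interquartile_range": float(np.percentile(x, 75) - np.percentile(x, 25)),
    }
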