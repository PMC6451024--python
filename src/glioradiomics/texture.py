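"""Gray-level quantization, GLCM and GLRLM texture descriptors in 3-D.

Masked intensities are quantized into ``n_levels`` equal-width bins
(half-open, top bin closed). Co-occurrence matrices are accumulated
symmetrically for each of the 13 unique 3-D directions at distances 1-3;
run-length matrices count maximal equal-level runs along each direction,
broken at the mask boundary. Everything operates on the mask's bounding box
and is fully vectorised; exhaustive brute-force oracles for small grids live
in the test suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import TumorMask, VolumeImage

_EPS = np.finfo(np.float64).tiny


@dataclass(frozen=True)
class GrayLevelQuantization:
    """Equal-width binning of masked intensities into 1..n_levels."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")


def quantize(values: np.ndarray, mask: np.ndarray, q: GrayLevelQuantization = GrayLevelQuantization()) -> np.ndarray:
    """Level grid (int, 0 outside mask, 1..n_levels inside).

    Bins are equal width over the within-mask [min, max]; the top bin is
    closed so the maximum maps to n_levels. A constant region maps to 1.
    """
    if not mask.any():
        raise ValueError("empty mask")
    levels = np.zeros(values.shape, dtype=np.int32)
    inside = values[mask]
    vmin, vmax = inside.min(), inside.max()
    if vmax == vmin:
        levels[mask] = 1
        return levels
    width = (vmax - vmin) / q.n_levels
    lv = np.floor((inside - vmin) / width).astype(np.int32) + 1
    np.clip(lv, 1, q.n_levels, out=lv)
    levels[mask] = lv
    return levels


def glcm_directions() -> list[tuple[int, int, int]]:
    """The 13 unique 3-D offsets: 26-neighbourhood deduplicated up to sign.

    Canonical form has the first nonzero component positive; order is
    lexicographic.
    """
    dirs = set()
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                d = (di, dj, dk)
                if d == (0, 0, 0):
                    continue
                for c in d:
                    if c != 0:
                        if c < 0:
                            d = (-di, -dj, -dk)
                        break
                dirs.add(d)
    return sorted(dirs)


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]):
    """Index pairs (a, b) of in-mask voxels with b = a + offset."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, levels.shape):
        if abs(o) >= n:
            return None
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    a = tuple(sl_a)
    b = tuple(sl_b)
    ok = mask[a] & mask[b]
    return levels[a][ok], levels[b][ok]


def compute_glcm(
    levels: np.ndarray,
    mask: np.ndarray,
    direction: tuple[int, int, int],
    distance: int = 1,
    n_levels: int | None = None,
) -> np.ndarray:
    """Symmetric co-occurrence counts for one (direction, distance) pair.

    Each unordered in-mask voxel pair contributes to (i, j) and (j, i).
    Returns the (n_levels x n_levels) count matrix; an all-zero matrix means
    no valid pair exists at this displacement.
    """
    if n_levels is None:
        n_levels = int(levels.max())
    offset = tuple(int(d) * int(distance) for d in direction)
    pairs = _shifted_pairs(levels, mask, offset)
    mat = np.zeros((n_levels, n_levels), dtype=np.float64)
    if pairs is None:
        return mat
    li, lj = pairs
    if li.size == 0:
        return mat
    idx = (li - 1) * n_levels + (lj - 1)
    counts = np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    mat = counts + counts.T
    return mat.astype(np.float64)


def normalize_glcm(mat: np.ndarray) -> np.ndarray:
    s = mat.sum()
    return mat / s if s > 0 else mat


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence descriptors from a normalized symmetric matrix.

    Degenerate matrices (single cell, or empty) fall back to zeros for
    variance-normalised terms; an all-zero matrix yields all-zero features.
    """
    ng = p.shape[0]
    total = p.sum()
    out = {name: 0.0 for name in _GLCM_KEYS}
    if total <= 0:
        return out
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((ii * p).sum())
    sigma2 = float(((ii - mu) ** 2 * p).sum())

    diff = np.abs(ii - jj)
    out["autocorrelation"] = float((ii * jj * p).sum())
    out["cluster_prominence"] = float(((ii + jj - 2 * mu) ** 4 * p).sum())
    out["cluster_shade"] = float(((ii + jj - 2 * mu) ** 3 * p).sum())
    out["cluster_tendency"] = float(((ii + jj - 2 * mu) ** 2 * p).sum())
    out["contrast"] = float((diff**2 * p).sum())
    if sigma2 > 1e-12:
        out["correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    out["dissimilarity"] = float((diff * p).sum())
    out["energy"] = float((p**2).sum())
    out["entropy"] = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    out["homogeneity"] = float((p / (1.0 + diff)).sum())
    out["inverse_difference_moment"] = float((p / (1.0 + diff**2)).sum())
    off = diff > 0
    out["inverse_variance"] = float((p[off] / diff[off] ** 2).sum())
    out["joint_average"] = mu
    out["max_probability"] = float(p.max())

    # difference distribution p_{|x-y|}(k), k = 0..ng-1
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.bincount(diff.astype(int).ravel(), weights=p.ravel(), minlength=ng)[:ng]
    da = float((k_diff * p_diff).sum())
    out["difference_average"] = da
    nz = p_diff > 0
    out["difference_entropy"] = float(-(p_diff[nz] * np.log2(p_diff[nz])).sum())
    out["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())

    # sum distribution p_{x+y}(k), k = 2..2*ng
    k_sum = np.arange(2 * ng + 1, dtype=np.float64)
    p_sum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    sa = float((k_sum * p_sum).sum())
    out["sum_average"] = sa
    nz = p_sum > 0
    out["sum_entropy"] = float(-(p_sum[nz] * np.log2(p_sum[nz])).sum())
    out["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())

    # information measures of correlation
    hxy = out["entropy"]
    px_nz = px[px > 0]
    hx = float(-(px_nz * np.log2(px_nz)).sum())
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    if hx > 1e-12:
        out["imc1"] = (hxy - hxy1) / hx
    if hxy2 >= hxy:
        out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


_GLCM_KEYS = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "inverse_difference_moment",
    "imc1",
    "imc2",
    "inverse_variance",
    "joint_average",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
)


def compute_glrlm(
    levels: np.ndarray,
    mask: np.ndarray,
    direction: tuple[int, int, int],
    n_levels: int | None = None,
) -> np.ndarray:
    """Run-length counts R[level-1, length-1] along one direction.

    A run is a maximal streak of in-mask voxels of equal level along the
    direction; mask boundaries break runs. Total counts equal the number of
    maximal runs.
    """
    if n_levels is None:
        n_levels = int(levels.max())
    d = tuple(int(x) for x in direction)
    shape = levels.shape
    max_run = int(np.ceil(np.sqrt(sum(n**2 for n in shape)))) + 1

    idx = np.argwhere(mask)
    if idx.size == 0:
        return np.zeros((n_levels, 1))

    def sample(pos: np.ndarray, arr: np.ndarray, fill):
        inb = np.all((pos >= 0) & (pos < np.array(shape)), axis=1)
        out = np.full(len(pos), fill, dtype=arr.dtype)
        p = pos[inb]
        out[inb] = arr[p[:, 0], p[:, 1], p[:, 2]]
        return out

    lv_here = levels[idx[:, 0], idx[:, 1], idx[:, 2]]
    prev = idx - np.array(d)
    prev_in = sample(prev, mask, False) & (sample(prev, levels, 0) == lv_here)
    starts = idx[~prev_in]
    start_lv = lv_here[~prev_in]

    # walk forward from each run start until level changes or mask ends
    lengths = np.ones(len(starts), dtype=np.int64)
    pos = starts + np.array(d)
    active = np.arange(len(starts))
    for _ in range(max_run):
        if active.size == 0:
            break
        cont = sample(pos, mask, False) & (sample(pos, levels, 0) == start_lv[active])
        active = active[cont]
        lengths[active] += 1
        pos = pos[cont] + np.array(d)

    max_len = int(lengths.max())
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(mat, (start_lv - 1, lengths - 1), 1.0)
    return mat


def glrlm_features(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 21 run-length descriptors from a count matrix.

    ``n_voxels`` is the number of in-mask voxels (for run percentage).
    """
    nr = r.sum()
    if nr <= 0:
        raise ValueError("empty run-length matrix")
    p = r / nr
    ng, nl = p.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)  # marginal over levels
    pr = p.sum(axis=0)  # marginal over lengths
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    out = {
        "short_run_emphasis": float((p / j**2).sum()),
        "long_run_emphasis": float((p * j**2).sum()),
        "gray_level_nonuniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        "gray_level_nonuniformity_normalized": float((pg**2).sum()),
        "run_length_nonuniformity": float((r.sum(axis=0) ** 2).sum() / nr),
        "run_length_nonuniformity_normalized": float((pr**2).sum()),
        "run_percentage": float(nr / n_voxels) if n_voxels > 0 else 0.0,
        "low_gray_level_run_emphasis": float((p / i**2).sum()),
        "high_gray_level_run_emphasis": float((p * i**2).sum()),
        "short_run_low_gray_level_emphasis": float((p / (i**2 * j**2)).sum()),
        "short_run_high_gray_level_emphasis": float((p * i**2 / j**2).sum()),
        "long_run_low_gray_level_emphasis": float((p * j**2 / i**2).sum()),
        "long_run_high_gray_level_emphasis": float((p * i**2 * j**2).sum()),
        "gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
        "run_length_variance": float((p * (j - mu_j) ** 2).sum()),
        "run_entropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "gray_level_mean": mu_i,
        "run_length_mean": mu_j,
        "gray_level_entropy": float(-(pg[pg > 0] * np.log2(pg[pg > 0])).sum()),
        "run_length_entropy": float(-(pr[pr > 0] * np.log2(pr[pr > 0])).sum()),
        "max_probability": float(p.max()),
    }
    return out
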