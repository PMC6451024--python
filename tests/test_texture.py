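"""Quantization, GLCM and GLRLM against hand values and brute-force oracles."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioradiomics.texture import (
    GrayLevelQuantization,
    compute_glcm,
    compute_glrlm,
    glcm_directions,
    glcm_features,
    glrlm_features,
    normalize_glcm,
    quantize,
)


# ---------------------------------------------------------------- oracles
def glcm_oracle(levels, mask, direction, distance, n_levels):
    """Count every ordered in-mask pair by explicit enumeration."""
    mat = np.zeros((n_levels, n_levels))
    off = tuple(d * distance for d in direction)
    for p in np.argwhere(mask):
        q = tuple(p + off)
        if all(0 <= c < n for c, n in zip(q, mask.shape)) and mask[q]:
            i, j = levels[tuple(p)] - 1, levels[q] - 1
            mat[i, j] += 1
            mat[j, i] += 1
    return mat


def glrlm_oracle(levels, mask, direction, n_levels):
    """Enumerate maximal runs by walking every line voxel by voxel."""
    runs = []
    d = np.array(direction)
    for p in np.argwhere(mask):
        prev = p - d
        inb = all(0 <= c < n for c, n in zip(prev, mask.shape))
        if inb and mask[tuple(prev)] and levels[tuple(prev)] == levels[tuple(p)]:
            continue  # not a run start
        length = 1
        cur = p + d
        while all(0 <= c < n for c, n in zip(cur, mask.shape)) and mask[tuple(cur)] and levels[tuple(cur)] == levels[tuple(p)]:
            length += 1
            cur = cur + d
        runs.append((levels[tuple(p)], length))
    max_len = max((l for _, l in runs), default=1)
    mat = np.zeros((n_levels, max_len))
    for lv, ln in runs:
        mat[lv - 1, ln - 1] += 1
    return mat


# ------------------------------------------------------------- quantize
class TestQuantize:
    def test_constant_region_maps_to_level_one(self):
        vals = np.full((3, 3, 3), 4.2)
        mask = np.ones((3, 3, 3), dtype=bool)
        assert (quantize(vals, mask)[mask] == 1).all()

    def test_integer_span_maps_to_floor_plus_one(self):
        vals = np.arange(32.0).reshape(2, 4, 4)
        mask = np.ones(vals.shape, dtype=bool)
        lv = quantize(vals, mask, GrayLevelQuantization(32))
        # top bin closed: value 31 (the max) stays at level 32
        assert np.array_equal(lv[mask], np.floor(vals[mask]).astype(int) + 1)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_rescaling_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 100, (4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.3
        mask[0, 0, 0] = True
        a = quantize(vals, mask)
        b = quantize(vals * scale + shift, mask)
        assert np.array_equal(a[mask], b[mask])


# ----------------------------------------------------------- directions
class TestDirections:
    def test_thirteen_directions(self):
        assert len(glcm_directions()) == 13

    def test_sign_deduplication(self):
        dirs = glcm_directions()
        assert (1, 0, 0) in dirs and (-1, 0, 0) not in dirs

    def test_equals_exhaustive_enumeration_modulo_negation(self):
        full = {d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)}
        got = set(glcm_directions())
        assert len(got) == len(full) // 2
        for d in full:
            neg = tuple(-x for x in d)
            assert (d in got) != (neg in got)


# ----------------------------------------------------------------- GLCM
class TestGLCM:
    def test_two_by_two_hand_example(self):
        # pairs (1,2) and (3,4) along the first axis
        levels = np.array([[1, 3], [2, 4]]).reshape(2, 2, 1)
        mask = np.ones((2, 2, 1), dtype=bool)
        p = normalize_glcm(compute_glcm(levels, mask, (1, 0, 0), 1, n_levels=4))
        expect = np.zeros((4, 4))
        expect[0, 1] = expect[1, 0] = expect[2, 3] = expect[3, 2] = 0.25
        assert np.allclose(p, expect)

    def test_constant_region_single_diagonal_entry(self):
        levels = np.ones((3, 3, 3), dtype=int)
        mask = np.ones((3, 3, 3), dtype=bool)
        p = normalize_glcm(compute_glcm(levels, mask, (0, 1, 0), 1, n_levels=2))
        assert p[0, 0] == 1.0 and p.sum() == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_and_oracle_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, 3))
        levels = rng.integers(1, 5, shape)
        mask = rng.random(shape) > 0.25
        for direction in [(1, 0, 0), (0, 1, 1), (1, -1, 1)]:
            for dist in (1, 2):
                got = compute_glcm(levels, mask, direction, dist, n_levels=4)
                assert np.array_equal(got, got.T)
                assert np.array_equal(got, glcm_oracle(levels, mask, direction, dist, 4))

    def test_all_13_directions_all_masks_up_to_6cubed(self, rng):
        for _ in range(3):
            levels = rng.integers(1, 4, (6, 6, 6))
            mask = rng.random((6, 6, 6)) > 0.4
            for direction in glcm_directions():
                for dist in (1, 2, 3):
                    got = compute_glcm(levels, mask, direction, dist, n_levels=3)
                    assert np.array_equal(got, glcm_oracle(levels, mask, direction, dist, 3))


class TestGLCMFeatures:
    def test_constant_region_degenerate_matrix(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        f = glcm_features(p)
        assert f["contrast"] == 0.0
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["correlation"] == 0.0  # zero-variance guard

    def test_hand_contrast_of_two_by_two_example(self):
        p = np.zeros((4, 4))
        p[0, 1] = p[1, 0] = p[2, 3] = p[3, 2] = 0.25
        assert glcm_features(p)["contrast"] == pytest.approx(1.0)

    def test_checkerboard_dissimilarity_equals_oracle(self):
        levels = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        mask = np.ones((4, 4, 1), dtype=bool)
        mat = compute_glcm(levels, mask, (1, 0, 0), 1, n_levels=2)
        f = glcm_features(normalize_glcm(mat))
        # oracle: enumerate pairs, mean |i-j|
        diffs = []
        for p in np.argwhere(mask):
            q = p + (1, 0, 0)
            if q[0] < 4:
                diffs.append(abs(int(levels[tuple(p)]) - int(levels[tuple(q)])))
        assert f["dissimilarity"] == pytest.approx(np.mean(diffs))


# ---------------------------------------------------------------- GLRLM
class TestGLRLM:
    def test_row_run_hand_example(self):
        levels = np.array([1, 1, 2]).reshape(3, 1, 1)
        mask = np.ones((3, 1, 1), dtype=bool)
        r = compute_glrlm(levels, mask, (1, 0, 0), n_levels=2)
        assert r[0, 1] == 1  # level 1, length 2
        assert r[1, 0] == 1  # level 2, length 1
        assert r.sum() == 2

    def test_distinct_levels_all_singleton_runs(self):
        levels = np.arange(1, 6).reshape(5, 1, 1)
        mask = np.ones((5, 1, 1), dtype=bool)
        r = compute_glrlm(levels, mask, (1, 0, 0), n_levels=5)
        assert r.sum() == 5 and r.shape[1] == 1

    def test_constant_row_single_run(self):
        levels = np.ones((7, 1, 1), dtype=int)
        mask = np.ones((7, 1, 1), dtype=bool)
        r = compute_glrlm(levels, mask, (1, 0, 0), n_levels=1)
        assert r.sum() == 1 and r[0, 6] == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_oracle_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, 3))
        levels = rng.integers(1, 4, shape)
        mask = rng.random(shape) > 0.3
        if not mask.any():
            mask[0, 0, 0] = True
        for direction in glcm_directions():
            got = compute_glrlm(levels, mask, direction, n_levels=3)
            exp = glrlm_oracle(levels, mask, direction, 3)
            w = max(got.shape[1], exp.shape[1])
            got = np.pad(got, ((0, 0), (0, w - got.shape[1])))
            exp = np.pad(exp, ((0, 0), (0, w - exp.shape[1])))
            assert np.array_equal(got, exp)


class TestGLRLMFeatures:
    def test_all_singleton_runs_unit_emphases(self):
        r = np.array([[3.0], [2.0]])
        f = glrlm_features(r, n_voxels=5)
        assert f["short_run_emphasis"] == 1.0
        assert f["long_run_emphasis"] == 1.0

    def test_hand_sre(self):
        # runs {(level 1, len 2), (level 2, len 1)}
        r = np.array([[0.0, 1.0], [1.0, 0.0]])
        f = glrlm_features(r, n_voxels=3)
        assert f["short_run_emphasis"] == pytest.approx(0.625)

    def test_single_run_unit_nonuniformities(self):
        r = np.zeros((3, 4))
        r[1, 3] = 1.0
        f = glrlm_features(r, n_voxels=4)
        assert f["run_length_nonuniformity"] == 1.0
        assert f["gray_level_nonuniformity"] == 1.0

    def test_empty_matrix_fails(self):
        with pytest.raises(ValueError):
            glrlm_features(np.zeros((2, 2)), n_voxels=4)
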