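"""First-order set, wavelet bands, the 936-vector and the z-transform."""

import numpy as np
import pandas as pd
import pytest

from glioradiomics.features import extract_all_features, z_transform_features
from glioradiomics.firstorder import first_order_features
from glioradiomics.manifest import DEFAULT_MANIFEST, FeatureManifest
from glioradiomics.wavelets import decimate_mask, wavelet_decompose

from .conftest import make_mask, make_volume


class TestManifest:
    def test_group_arithmetic(self):
        m = DEFAULT_MANIFEST
        assert len(m.first_order) == 17
        n_texture = len(m.glcm) * len(m.distances) + len(m.glrlm)
        assert n_texture == 87
        assert len(m.first_order) + n_texture == 104
        assert len(m) == 936

    def test_names_unique_and_structured(self):
        names = DEFAULT_MANIFEST.names
        assert len(set(names)) == 936
        assert all(n.count(":") == 2 for n in names)
        wavelet_sourced = [n for n in names if not n.startswith("original:")]
        assert len(wavelet_sourced) == 832

    def test_bad_split_rejected(self):
        with pytest.raises(AssertionError):
            FeatureManifest(glrlm=DEFAULT_MANIFEST.glrlm[:-1])

    def test_json_roundtrip(self, tmp_path):
        import json

        path = DEFAULT_MANIFEST.to_json(tmp_path / "manifest.json")
        payload = json.loads(path.read_text())
        assert payload["n_features"] == 936
        assert payload["names"] == list(DEFAULT_MANIFEST.names)


class TestFirstOrder:
    def test_constant_region(self):
        vals = np.full((3, 3, 3), 5.0)
        f = first_order_features(vals, np.ones((3, 3, 3), bool))
        assert f["range"] == 0.0
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0

    def test_three_values(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1, 2, 3]
        f = first_order_features(vals, np.ones((3, 1, 1), bool))
        assert f["mean"] == 2.0
        assert f["median"] == 2.0
        assert f["maximum"] == 3.0
        assert f["variance"] == pytest.approx(1.0)  # sample variance

    def test_exactly_17_features(self, rng):
        f = first_order_features(rng.random((4, 4, 4)), np.ones((4, 4, 4), bool))
        assert len(f) == 17
        assert set(f) == set(DEFAULT_MANIFEST.first_order)


class TestWavelets:
    def test_eight_bands(self, rng):
        bands = wavelet_decompose(rng.standard_normal((8, 8, 8)))
        assert len(bands) == 8
        assert set(bands) == {"LLL", "HLL", "LHL", "HHL", "LLH", "HLH", "LHH", "HHH"}

    def test_constant_volume_high_pass_bands_vanish(self):
        bands = wavelet_decompose(np.full((8, 8, 8), 3.0))
        for key, arr in bands.items():
            if "H" in key:
                assert np.abs(arr).max() == 0.0
            else:
                assert np.abs(arr).max() > 0

    def test_parseval_energy_identity(self, rng):
        x = rng.standard_normal((8, 8, 8))
        bands = wavelet_decompose(x)
        e_bands = sum((v**2).sum() for v in bands.values())
        e_in = (x**2).sum()
        assert abs(e_bands - e_in) / e_in < 1e-8

    def test_band_letters_follow_axes(self):
        # a volume varying only along axis 2 puts all detail energy in LLH
        x = np.zeros((8, 8, 8))
        x[:, :, ::2] = 1.0
        bands = wavelet_decompose(x)
        detail = {k: (v**2).sum() for k, v in bands.items() if "H" in k}
        assert detail["LLH"] == max(detail.values())
        assert all(v == 0 for k, v in detail.items() if k != "LLH")

    def test_odd_dims_handled(self, rng):
        bands = wavelet_decompose(rng.standard_normal((9, 8, 7)))
        assert bands["LLL"].shape == (5, 4, 4)

    def test_mask_decimation_picks_even_lattice(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        sub = decimate_mask(mask, (4, 4, 4))
        assert np.array_equal(sub, mask[::2, ::2, ::2])


class TestExtraction:
    def test_vector_length_and_order(self, gbm_subject):
        fv = extract_all_features(gbm_subject.ce_t1w, gbm_subject.mask_truth)
        assert len(fv) == 936
        assert list(fv.index) == list(DEFAULT_MANIFEST.names)
        assert fv.notna().all()

    def test_deterministic(self, gbm_subject):
        a = extract_all_features(gbm_subject.ce_t1w, gbm_subject.mask_truth)
        b = extract_all_features(gbm_subject.ce_t1w, gbm_subject.mask_truth)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_tiny_mask_yields_full_length_vector(self):
        vals = np.random.default_rng(0).random((10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[5, 5, 5] = mask[5, 5, 6] = True
        with pytest.warns(UserWarning):
            fv = extract_all_features(make_volume(vals), make_mask(mask))
        assert len(fv) == 936

    def test_heterogeneous_class_has_higher_texture_contrast(self):
        """GLCM contrast separates the two phantom classes (rank test)."""
        from scipy.stats import mannwhitneyu

        from glioradiomics.phantoms import PhantomSpec, generate_subject

        gbm_c, pcnsl_c = [], []
        for i in range(8):
            g = generate_subject(PhantomSpec(class_label="glioblastoma", seed=100 + i))
            p = generate_subject(PhantomSpec(class_label="PCNSL", seed=100 + i))
            gbm_c.append(extract_all_features(g.ce_t1w, g.mask_truth)["original:glcm_d1:contrast"])
            pcnsl_c.append(extract_all_features(p.ce_t1w, p.mask_truth)["original:glcm_d1:contrast"])
        res = mannwhitneyu(gbm_c, pcnsl_c, alternative="greater")
        assert res.pvalue < 0.01


class TestZTransform:
    def test_fit_column_maps_to_unit_scores(self):
        table = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z, _ = z_transform_features(table)
        assert np.allclose(z["f"], [-1, 0, 1])

    def test_training_rows_standardized(self, rng):
        table = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        z, _ = z_transform_features(table, fit_rows=table.index[:15])
        fit = z.iloc[:15]
        assert np.abs(fit.mean(axis=0)).max() < 1e-10
        assert np.abs(fit.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_validation_row_at_training_mean_is_zero(self, rng):
        table = pd.DataFrame(rng.random((10, 4)))
        mean_row = table.iloc[:10].mean()
        table.loc[10] = mean_row
        z, scaler = z_transform_features(table, fit_rows=table.index[:10])
        assert np.abs(z.loc[10]).max() < 1e-12

    def test_constant_feature_warned_and_zeroed(self):
        table = pd.DataFrame({"f": [1.0, 1.0, 1.0], "g": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            z, _ = z_transform_features(table)
        assert (z["f"] == 0).all()
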