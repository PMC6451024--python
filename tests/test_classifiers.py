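"""Metric-1 grid, GLM boosting, and the MLP ensemble of Metric 2."""

import numpy as np
import pandas as pd
import pytest

from glioradiomics.classifiers import (
    ClassifierSpec,
    CVScheme,
    GLMBoost,
    make_classifier,
    train_classifier_grid,
)
from glioradiomics.evaluation import compute_auc
from glioradiomics.mlp import (
    DEFAULT_ARCHITECTURES,
    EnsembleMember,
    MLPArchitecture,
    MLPNet,
    TrainedEnsemble,
    TrainingConfig,
    predict_ensemble,
    train_mlp,
    train_mlp_ensemble,
)


def separable_features(rng, n_per_class=60, n_features=5, gap=4.0):
    X = np.vstack(
        [
            rng.standard_normal((n_per_class, n_features)),
            rng.standard_normal((n_per_class, n_features)) + gap,
        ]
    )
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestGLMBoost:
    def test_separable_data_perfectly_ranked(self, rng):
        X, y = separable_features(rng)
        m = GLMBoost().fit(X, y)
        assert compute_auc(m.decision_function(X), y) == 1.0

    def test_importances_track_signal(self, rng):
        n = 200
        X = rng.standard_normal((n, 6))
        y = (X[:, 2] > 0).astype(int)
        m = GLMBoost().fit(X, y)
        assert np.argmax(m.feature_importances()) == 2

    def test_probabilities_in_unit_interval(self, rng):
        X, y = separable_features(rng, 20)
        p = GLMBoost().fit(X, y).predict_proba(X)
        assert p.shape == (40, 2)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestGrid:
    def test_nine_models_and_cv_run_count(self, rng):
        X, y = separable_features(np.random.default_rng(7), n_per_class=60)
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        cv = CVScheme(n_folds=5, n_repeats=2, seed=0)
        grid = train_classifier_grid(table, y, cv=cv, seed=0)
        assert len(grid) == 9
        assert {(s, c) for s, c in grid} == {
            (s, c)
            for s in ("mrmr", "cfs", "backward")
            for c in ("rbf_svm", "glm_boost", "regularized_rf")
        }
        for gm in grid.values():
            assert len(gm.fold_aucs) == cv.n_runs == 10

    def test_full_scheme_counts_100_runs(self):
        assert CVScheme(n_folds=10, n_repeats=10).n_runs == 100

    def test_separable_features_score_high_everywhere(self):
        rng = np.random.default_rng(7)
        X, y = separable_features(rng, n_per_class=60)
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        grid = train_classifier_grid(table, y, cv=CVScheme(n_folds=5, n_repeats=1, seed=7), seed=7)
        for gm in grid.values():
            assert gm.auc_mean >= 0.95

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(kind="nonsense")


class TestArchitectures:
    @pytest.mark.parametrize(
        "s,widths",
        [
            ("100-10", (100, 10)),
            ("500-100-10", (500, 100, 10)),
            ("500-100-50-10", (500, 100, 50, 10)),
            ("500-250-100-50-20", (500, 250, 100, 50, 20)),
            ("500-250-100-50-10", (500, 250, 100, 50, 10)),
            ("750-500-250-100-50-10", (750, 500, 250, 100, 50, 10)),
        ],
    )
    def test_dash_string_parsing(self, s, widths):
        assert MLPArchitecture.parse(s).hidden == widths

    def test_default_sweep_has_four_networks(self):
        assert len(DEFAULT_ARCHITECTURES) == 4

    def test_bad_strings_rejected(self):
        with pytest.raises(ValueError):
            MLPArchitecture.parse("100-abc")
        with pytest.raises(ValueError):
            MLPArchitecture(hidden=())


class TestMLP:
    def test_default_hyperparameters(self):
        cfg = TrainingConfig()
        assert cfg.batch_size == 32
        assert cfg.momentum == 0.25
        assert cfg.learning_rate == 1e-3
        assert cfg.weight_decay == 0.0
        assert cfg.class_weight_pcnsl == 1.467

    def test_unit_class_weight_reduces_to_unweighted_loss(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.integers(0, 2, 40)
        net = MLPNet(MLPArchitecture.parse("8-4"), 4, seed=0)
        w1 = net.loss(X, y, np.array([1.0, 1.0]))
        probs = net.predict_proba(X)
        unweighted = float(-np.log(np.clip(probs[np.arange(40), y], 1e-12, None)).mean())
        assert w1 == pytest.approx(unweighted, abs=1e-12)

    def test_training_loss_decreases_on_smoothed_window(self, rng):
        X, y = separable_features(rng, 30, gap=2.0)
        _, history = train_mlp(X, y, MLPArchitecture.parse("16-8"), TrainingConfig(max_epochs=60, seed=0), seed=0)
        first = np.mean(history[:10])
        last = np.mean(history[-10:])
        assert last < first

    def test_ensemble_has_10_members_from_distinct_folds(self):
        rng = np.random.default_rng(0)
        X, y = separable_features(rng, 50)
        ens = train_mlp_ensemble(X, y, "100-10", TrainingConfig(max_epochs=30, seed=0))
        assert len(ens.members) == 10
        assert len({m.fold_index for m in ens.members}) == 10

    def test_separable_training_accuracy_perfect(self):
        rng = np.random.default_rng(1)
        X, y = separable_features(rng, 100)
        ens = train_mlp_ensemble(X, y, "100-10", TrainingConfig(max_epochs=50, seed=0))
        pred = predict_ensemble(ens, X)
        assert (pred["label"] == y).mean() == 1.0

    def test_ensemble_deterministic(self):
        rng = np.random.default_rng(3)
        X, y = separable_features(rng, 30, gap=1.0)
        cfg = TrainingConfig(max_epochs=20, seed=4)
        a = train_mlp_ensemble(X, y, "100-10", cfg)
        b = train_mlp_ensemble(X, y, "100-10", cfg)
        assert np.array_equal(a.member_probs(X), b.member_probs(X))


class TestMajorityVote:
    def _fixed_ensemble(self, member_probs):
        """Ensemble stub whose members return fixed PCNSL probabilities."""

        class _FixedNet:
            def __init__(self, p):
                self.p = np.atleast_1d(p)

            def predict_proba(self, X):
                return np.column_stack([1 - self.p, self.p])

        members = [
            EnsembleMember(net=_FixedNet(p), fold_index=i, scaler_mean=np.zeros(1), scaler_sd=np.ones(1))
            for i, p in enumerate(member_probs)
        ]
        return TrainedEnsemble(arch=MLPArchitecture.parse("100-10"), members=members)

    def test_vote_follows_mode(self):
        probs = [0.1] * 7 + [0.9] * 3  # 7 GBM votes, 3 PCNSL
        ens = self._fixed_ensemble([[p] for p in probs])
        pred = predict_ensemble(ens, np.zeros((1, 1)))
        assert pred["label"][0] == 0

    def test_tie_resolved_by_mean_probability(self):
        probs = [0.05] * 5 + [0.95, 0.95, 0.95, 0.95, 0.9]  # 5-5 tie, mean 0.475+...
        ens = self._fixed_ensemble([[p] for p in probs])
        pred = predict_ensemble(ens, np.zeros((1, 1)))
        mean_p = np.mean(probs)
        assert pred["votes"][0] == 5
        assert pred["label"][0] == int(mean_p >= 0.5)

    def test_identical_members_equal_single_member(self, rng):
        p = rng.random(6)
        ens10 = self._fixed_ensemble([p] * 10)
        ens1 = self._fixed_ensemble([p] * 1)
        X = np.zeros((6, 1))
        a, b = predict_ensemble(ens10, X), predict_ensemble(ens1, X)
        assert np.array_equal(a["label"], b["label"])
        assert np.allclose(a["score"], b["score"])

    def test_vote_equals_direct_counting_oracle(self, rng):
        member_probs = [rng.random(8) for _ in range(10)]
        ens = self._fixed_ensemble(member_probs)
        pred = predict_ensemble(ens, np.zeros((8, 1)))
        stacked = np.stack([np.atleast_1d(p) for p in member_probs])
        for i in range(8):
            votes = (stacked[:, i] >= 0.5).sum()
            if votes != 5:
                assert pred["label"][i] == int(votes > 5)

    def test_dimension_mismatch_fails(self):
        ens = self._fixed_ensemble([[0.5]] * 10)
        with pytest.raises(ValueError):
            predict_ensemble(ens, np.zeros((2, 3)))


class TestLogisticBaseline:
    def test_label_feature_gives_perfect_cv_auc(self, rng):
        y = rng.integers(0, 2, 100)
        X = y[:, None].astype(float)
        m = make_classifier("logistic").fit(X, y)
        assert compute_auc(m.decision_scores(X), y) == 1.0

    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(3)
        n = 200
        X = rng.standard_normal((n, 5))
        y = rng.integers(0, 2, n)
        from sklearn.model_selection import StratifiedKFold

        aucs = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=3).split(X, y):
            m = make_classifier("logistic", seed=3).fit(X[tr], y[tr])
            aucs.append(compute_auc(m.decision_scores(X[te]), y[te]))
        assert 0.35 <= np.mean(aucs) <= 0.65
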