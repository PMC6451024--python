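"""Metric-1 classifiers and the selector x classifier training grid.

Three classifiers pair with the three selectors for the 9-model grid:

* ``rbf_svm`` — RBF-kernel SVM with a small inner grid over C and gamma,
  chosen by inner 5-fold CV AUC;
* ``glm_boost`` — componentwise gradient boosting with linear base learners
  on the binomial deviance (mstop 100, step 0.1), the standard form of the
  boosted GLM; coefficient magnitudes double as feature importances;
* ``regularized_rf`` — importance-penalised feature admission (a screening
  forest admits features with importance >= (1 - penalty) x max), then a
  500-tree random forest on the admitted set.

Each grid model is scored by repeated stratified 10-fold CV with selection
nested inside each training fold (leakage-safe default), keeping the full
AUC distribution for the RSD stability measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

from .evaluation import compute_auc, rsd_stability
from .selection import SELECTORS, SelectionResult

CLASSIFIER_KINDS = ("rbf_svm", "glm_boost", "regularized_rf", "logistic")


@dataclass
class ClassifierSpec:
    kind: str = "glm_boost"
    svm_C_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    svm_gamma_factors: tuple[float, ...] = (0.5, 1.0, 2.0)
    boost_mstop: int = 100
    boost_step: float = 0.1
    rf_n_trees: int = 500
    rf_penalty: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.boost_mstop <= 0 or self.boost_step <= 0 or self.rf_n_trees <= 0:
            raise ValueError("hyper-parameters must be positive")


class GLMBoost:
    """Componentwise gradient boosting with linear base learners (logit loss).

    Features are standardised internally; at each of ``mstop`` iterations the
    single centred feature that best fits the current negative gradient gets
    a ``step``-damped coefficient update. The fitted model is linear, and
    |coefficient| per feature serves as its importance.
    """

    def __init__(self, mstop: int = 100, step: float = 0.1):
        self.mstop = mstop
        self.step = step

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GLMBoost":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mu) / self._sd
        n, p = Xs.shape
        denom = (Xs**2).sum(axis=0)
        denom = np.where(denom > 0, denom, 1.0)

        ybar = y.mean()
        self.intercept_ = float(np.log(ybar / (1 - ybar))) if 0 < ybar < 1 else 0.0
        coef = np.zeros(p)
        f = np.full(n, self.intercept_)
        for _ in range(self.mstop):
            prob = 1.0 / (1.0 + np.exp(-f))
            u = y - prob  # negative gradient of the binomial deviance
            num = Xs.T @ u
            gain = num**2 / denom
            j = int(np.argmax(gain))
            beta = num[j] / denom[j]
            coef[j] += self.step * beta
            f += self.step * beta * Xs[:, j]
        self.coef_ = coef
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self._mu) / self._sd
        return self.intercept_ + Xs @ self.coef_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p1, p1])

    def feature_importances(self) -> np.ndarray:
        return np.abs(self.coef_)


class FittedClassifier:
    """Uniform facade over the heterogeneous estimators."""

    def __init__(self, kind: str, spec: ClassifierSpec, seed: int):
        self.kind = kind
        self.spec = spec
        self.seed = seed
        self._model = None
        self._admitted: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FittedClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int)
        spec = self.spec
        if self.kind == "glm_boost":
            self._model = GLMBoost(spec.boost_mstop, spec.boost_step).fit(X, y)
        elif self.kind == "rbf_svm":
            self._model = self._fit_svm(X, y)
        elif self.kind == "regularized_rf":
            self._model = self._fit_rrf(X, y)
        elif self.kind == "logistic":
            self._model = LogisticRegression(C=1e4, max_iter=5000, random_state=self.seed).fit(X, y)
        else:  # pragma: no cover
            raise ValueError(self.kind)
        return self

    def _fit_svm(self, X: np.ndarray, y: np.ndarray) -> SVC:
        d = X.shape[1]
        var = X.var()
        gamma0 = 1.0 / (d * var) if var > 0 else 1.0 / d
        best, best_auc = None, -np.inf
        n_splits = min(5, int(np.bincount(y).min()))
        for C in self.spec.svm_C_grid:
            for gf in self.spec.svm_gamma_factors:
                gamma = gamma0 * gf
                if n_splits >= 2:
                    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
                    aucs = []
                    for tr, te in skf.split(X, y):
                        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                            continue
                        m = SVC(kernel="rbf", C=C, gamma=gamma, random_state=self.seed).fit(X[tr], y[tr])
                        aucs.append(compute_auc(m.decision_function(X[te]), y[te]))
                    score = float(np.mean(aucs)) if aucs else -np.inf
                else:
                    score = -np.inf
                if score > best_auc:
                    best_auc, best = score, (C, gamma)
        if best is None:
            best = (1.0, gamma0)
        return SVC(kernel="rbf", C=best[0], gamma=best[1], random_state=self.seed).fit(X, y)

    def _fit_rrf(self, X: np.ndarray, y: np.ndarray) -> RandomForestClassifier:
        screen = RandomForestClassifier(n_estimators=100, random_state=self.seed, n_jobs=1).fit(X, y)
        imp = screen.feature_importances_
        thr = (1.0 - self.spec.rf_penalty) * imp.max()
        admitted = np.flatnonzero(imp >= thr)
        if admitted.size == 0:
            admitted = np.array([int(np.argmax(imp))])
        self._admitted = admitted
        return RandomForestClassifier(
            n_estimators=self.spec.rf_n_trees, random_state=self.seed, n_jobs=1
        ).fit(X[:, admitted], y)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous score increasing with P(positive class)."""
        X = np.asarray(X, dtype=np.float64)
        if self.kind == "rbf_svm":
            return self._model.decision_function(X)
        if self.kind == "regularized_rf":
            return self._model.predict_proba(X[:, self._admitted])[:, 1]
        return self._model.predict_proba(X)[:, 1]

    def feature_importances(self) -> np.ndarray:
        if self.kind == "glm_boost":
            return self._model.feature_importances()
        raise NotImplementedError(f"no importances for {self.kind}")


def make_classifier(kind: str, spec: ClassifierSpec | None = None, seed: int = 0) -> FittedClassifier:
    spec = spec or ClassifierSpec(kind=kind, seed=seed)
    return FittedClassifier(kind, spec, seed)


@dataclass
class GridModel:
    selector: str
    classifier: str
    fold_aucs: list[float]
    auc_mean: float
    rsd_percent: float
    selection: SelectionResult
    model: FittedClassifier
    feature_names: list[str]

    def score(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.decision_scores(table[self.feature_names].to_numpy(dtype=np.float64))


@dataclass
class CVScheme:
    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0

    def splitter(self) -> RepeatedStratifiedKFold:
        return RepeatedStratifiedKFold(n_splits=self.n_folds, n_repeats=self.n_repeats, random_state=self.seed)

    @property
    def n_runs(self) -> int:
        return self.n_folds * self.n_repeats


def train_classifier_grid(
    table: pd.DataFrame,
    labels: np.ndarray,
    selectors: Iterable[str] = ("mrmr", "cfs", "backward"),
    classifiers: Iterable[str] = ("rbf_svm", "glm_boost", "regularized_rf"),
    cv: CVScheme = CVScheme(),
    nested_selection: bool = True,
    seed: int = 0,
) -> dict[tuple[str, str], GridModel]:
    """Fit and CV-score the full selector x classifier grid.

    With ``nested_selection`` (default) the selector runs inside every
    training fold; the non-nested variant selects once on the full training
    table before CV. Final models (for external application) are refit on
    all rows with selection on all rows.
    """
    selectors = list(selectors)
    classifiers = list(classifiers)
    y = np.asarray(labels).astype(int)
    if np.bincount(y, minlength=2).min() < cv.n_folds:
        # stratified folds need >= 1 subject per class per fold; the paper's
        # scheme additionally wants >= 2 to train on
        if np.bincount(y, minlength=2).min() < 2:
            raise ValueError("need >= 2 subjects per class")

    fold_scores: dict[tuple[str, str], list[float]] = {(s, c): [] for s in selectors for c in classifiers}
    global_selection = None
    if not nested_selection:
        global_selection = {s: SELECTORS[s](table, y, seed) for s in selectors}

    for i_split, (tr, te) in enumerate(cv.splitter().split(table.to_numpy(), y)):
        if len(np.unique(y[te])) < 2:
            raise ValueError(f"degenerate fold {i_split}: single class in test split")
        tr_table = table.iloc[tr]
        for s in selectors:
            sel = global_selection[s] if global_selection else SELECTORS[s](tr_table, y[tr], seed + i_split)
            cols = sel.selected
            Xtr = tr_table[cols].to_numpy(dtype=np.float64)
            Xte = table.iloc[te][cols].to_numpy(dtype=np.float64)
            for c in classifiers:
                clf = make_classifier(c, seed=seed)
                clf.fit(Xtr, y[tr])
                fold_scores[(s, c)].append(compute_auc(clf.decision_scores(Xte), y[te]))

    grid: dict[tuple[str, str], GridModel] = {}
    final_selection = {s: SELECTORS[s](table, y, seed) for s in selectors}
    for s in selectors:
        cols = final_selection[s].selected
        X = table[cols].to_numpy(dtype=np.float64)
        for c in classifiers:
            clf = make_classifier(c, seed=seed).fit(X, y)
            aucs = fold_scores[(s, c)]
            stab = rsd_stability(aucs)
            grid[(s, c)] = GridModel(
                selector=s,
                classifier=c,
                fold_aucs=aucs,
                auc_mean=stab.auc_mean,
                rsd_percent=stab.rsd_percent,
                selection=final_selection[s],
                model=clf,
                feature_names=cols,
            )
    return grid
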