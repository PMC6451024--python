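"""The three feature selectors: mRMR, CFS, and backward elimination.

* **mRMR** — greedy MID criterion: at each step pick
  argmax_f [ I(f; y) − mean_{s in S} I(f; s) ], with mutual information on
  4 equal-frequency bins.
* **CFS** — best-first forward search maximising the subset merit
  M_S = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) with |Pearson| feature–feature
  correlation and point-biserial feature–class correlation; the search stops
  after 5 consecutive non-improving expansions.
* **Backward elimination** — univariate-AUC prefilter to the top 100
  features, then recursive elimination dropping the least-important feature
  under the inner model (componentwise GLM boosting by default), scoring
  every set by inner 5-fold CV AUC and returning the best-scoring set.

All three are pure functions of (table, labels, config, seed); ties break by
column (manifest) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluation import compute_auc

_MI_BINS = 4


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    trace: list[dict] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate selected features")

    def to_dict(self) -> dict:
        return {"method": self.method, "selected": self.selected, "trace": self.trace, "seed": self.seed}


def _discretize(X: np.ndarray, n_bins: int = _MI_BINS) -> np.ndarray:
    """Equal-frequency binning per column into codes 0..n_bins-1."""
    n, p = X.shape
    out = np.empty((n, p), dtype=np.int8)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(p):
        edges = np.quantile(X[:, j], qs)
        out[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return out


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """MI (nats) for a stack of contingency tables, shape (..., a, b)."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / np.maximum(n, 1)
    pa = p.sum(axis=-1, keepdims=True)
    pb = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (pa * pb))
    return np.nansum(term, axis=(-2, -1))


def _mi_vs_vector(disc: np.ndarray, vec: np.ndarray, n_vec_states: int) -> np.ndarray:
    """MI between every column of `disc` and a single discrete vector."""
    n, p = disc.shape
    counts = np.zeros((p, _MI_BINS, n_vec_states))
    for a in range(_MI_BINS):
        col_is_a = disc == a  # (n, p)
        for b in range(n_vec_states):
            counts[:, a, b] = col_is_a[vec == b].sum(axis=0)
    return _mi_from_counts(counts)


def mrmr_criterion(disc: np.ndarray, y: np.ndarray, subset: list[int], candidate: int, relevance: np.ndarray) -> float:
    """The MID score of adding `candidate` to `subset` (for oracle checks)."""
    red = 0.0
    if subset:
        red = float(
            np.mean([_mi_vs_vector(disc[:, [candidate]], disc[:, s], _MI_BINS)[0] for s in subset])
        )
    return float(relevance[candidate]) - red


def select_mrmr(table: pd.DataFrame, labels: np.ndarray, k: int = 20) -> SelectionResult:
    """Greedy mRMR (MID variant)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.shape[1]:
        raise ValueError(f"k={k} exceeds {table.shape[1]} features")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    X = table.to_numpy(dtype=np.float64)
    disc = _discretize(X)
    relevance = _mi_vs_vector(disc, y, 2)

    selected: list[int] = []
    trace: list[dict] = []
    redundancy_sum = np.zeros(X.shape[1])
    available = np.ones(X.shape[1], dtype=bool)
    for _ in range(k):
        if selected:
            score = relevance - redundancy_sum / len(selected)
        else:
            score = relevance.copy()
        score[~available] = -np.inf
        best = int(np.argmax(score))  # argmax takes the first max -> manifest-order ties
        selected.append(best)
        available[best] = False
        trace.append({"feature": table.columns[best], "score": float(score[best])})
        redundancy_sum += _mi_vs_vector(disc, disc[:, best], _MI_BINS)
    return SelectionResult("mrmr", [table.columns[i] for i in selected], trace)


def cfs_merit(r_cf_mean: float, r_ff_mean: float, k: int) -> float:
    """Subset merit M_S = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)."""
    denom = np.sqrt(k + k * (k - 1) * r_ff_mean)
    return float(k * r_cf_mean / denom) if denom > 0 else 0.0


def select_cfs(table: pd.DataFrame, labels: np.ndarray, max_stale: int = 5) -> SelectionResult:
    """Correlation-based feature selection with best-first forward search."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = np.asarray(labels).astype(float)
    X = table.to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.all():
        import warnings

        warnings.warn(f"{int((~usable).sum())} zero-variance feature(s) skipped by CFS")
    Xc = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    yc = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    r_cf = np.abs(Xc.T @ yc / len(y))  # point-biserial == Pearson with 0/1 labels
    r_cf[~usable] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(Xc, rowvar=False)) if X.shape[1] > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)

    p = X.shape[1]

    def merit_of(subset: tuple[int, ...]) -> float:
        k = len(subset)
        rcf = r_cf[list(subset)].mean()
        if k == 1:
            return float(rcf)
        sub = np.array(subset)
        rff = (corr[np.ix_(sub, sub)].sum() - k) / (k * (k - 1))
        return cfs_merit(rcf, rff, k)

    # best-first: expand the best open subset by one feature at a time
    start = (int(np.argmax(r_cf)),)
    open_list: list[tuple[float, tuple[int, ...]]] = [(merit_of(start), start)]
    best_merit, best_subset = open_list[0]
    visited = {start}
    trace = [{"subset": [table.columns[i] for i in start], "merit": best_merit}]
    stale = 0
    while open_list and stale < max_stale:
        open_list.sort(key=lambda t: (-t[0], t[1]))
        cur_merit, cur = open_list.pop(0)
        improved = False
        for j in range(p):
            if j in cur or not usable[j]:
                continue
            cand = tuple(sorted(cur + (j,)))
            if cand in visited:
                continue
            visited.add(cand)
            m = merit_of(cand)
            open_list.append((m, cand))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, cand
                improved = True
        trace.append({"expanded": [table.columns[i] for i in cur], "merit": cur_merit})
        stale = 0 if improved else stale + 1
    ordered = sorted(best_subset)
    return SelectionResult("cfs", [table.columns[i] for i in ordered], trace)


def _univariate_auc(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|AUC - 0.5| screening score per feature (direction-free)."""
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        scores[j] = abs(compute_auc(X[:, j], y) - 0.5)
    return scores


def select_backward_elimination(
    table: pd.DataFrame,
    labels: np.ndarray,
    inner_model: str = "glm_boost",
    seed: int = 0,
    prefilter: int = 100,
    inner_folds: int = 5,
) -> SelectionResult:
    """Recursive backward elimination scored by inner CV AUC."""
    from .classifiers import make_classifier  # local import avoids a cycle

    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = np.asarray(labels).astype(int)
    X = table.to_numpy(dtype=np.float64)

    order = np.argsort(-_univariate_auc(X, y), kind="stable")
    keep = sorted(order[: min(prefilter, X.shape[1])])
    current = list(keep)

    rng = np.random.default_rng(seed)

    def cv_auc(cols: list[int], fold_seed: int) -> float:
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=fold_seed)
        aucs = []
        for tr, te in skf.split(X, y):
            clf = make_classifier(inner_model, seed=fold_seed)
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            s = clf.decision_scores(X[np.ix_(te, cols)])
            if len(np.unique(y[te])) < 2:
                continue
            aucs.append(compute_auc(s, y[te]))
        return float(np.mean(aucs))

    inner_seed = int(rng.integers(2**31))
    trace: list[dict] = []
    best_cols = list(current)
    best_score = cv_auc(current, inner_seed)
    while len(current) > 1:
        clf = make_classifier(inner_model, seed=inner_seed)
        clf.fit(X[:, current], y)
        imp = clf.feature_importances()
        drop_pos = int(np.argmin(imp))  # first minimum -> manifest-order ties
        dropped = current.pop(drop_pos)
        score = cv_auc(current, inner_seed)
        trace.append({"dropped": table.columns[dropped], "cv_auc": score, "n_left": len(current)})
        if score > best_score + 1e-12:
            best_score, best_cols = score, list(current)
    return SelectionResult(
        "backward",
        [table.columns[i] for i in sorted(best_cols)],
        trace,
        seed=seed,
    )


SELECTORS = {
    "mrmr": lambda table, y, seed: select_mrmr(table, y, k=min(20, table.shape[1])),
    "cfs": lambda table, y, seed: select_cfs(table, y),
    "backward": lambda table, y, seed: select_backward_elimination(table, y, seed=seed),
}
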