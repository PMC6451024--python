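"""ROC/AUC evaluation, Youden operating points, bootstrap CIs, RSD stability.

AUC is the Mann–Whitney probability that a random positive outscores a
random negative (ties count 1/2). The operating threshold maximises the
Youden index J = sensitivity + specificity − 1 over midpoints of adjacent
unique scores (plus the two infinite endpoints); J-ties resolve toward the
higher-specificity threshold. Confidence intervals are stratified percentile
bootstrap. Model stability is the relative standard deviation of the
cross-validated AUCs, (SD/mean) x 100 with the sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def compute_auc(scores, labels) -> float:
    """Mann–Whitney AUC; labels are 0/1 with 1 = positive (PCNSL)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _operating_point(s: np.ndarray, y: np.ndarray, thr: float) -> tuple[float, float, float]:
    pred = s >= thr
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(y)
    return sens, spec, acc


def youden_threshold(scores, labels) -> dict[str, float]:
    """Operating point maximising J = sens + spec − 1."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    best = None
    for thr in candidates:
        sens, spec, acc = _operating_point(s, y, thr)
        j = sens + spec - 1.0
        # strict > keeps the earlier candidate on J-ties; among equal-J points
        # prefer the higher-specificity one
        if best is None or j > best["j"] + 1e-12 or (abs(j - best["j"]) <= 1e-12 and spec > best["specificity"]):
            best = {"threshold": float(thr), "j": float(j), "sensitivity": sens, "specificity": spec, "accuracy": acc}
    return best  # type: ignore[return-value]


def bootstrap_ci(scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[i] = compute_auc(s[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1.0 - alpha))


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")
        if not (self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12):
            raise ValueError("CI must contain the point AUC")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("auc", "ci_low", "ci_high", "threshold", "sensitivity", "specificity", "accuracy", "n_pos", "n_neg")}


def evaluate_scores(scores, labels, seed: int = 0, n_boot: int = 2000) -> ROCResult:
    y = np.asarray(labels).astype(int)
    auc = compute_auc(scores, y)
    ci = bootstrap_ci(scores, y, n_boot=n_boot, seed=seed)
    op = youden_threshold(scores, y)
    return ROCResult(
        auc=auc,
        ci_low=min(ci[0], auc),
        ci_high=max(ci[1], auc),
        threshold=op["threshold"],
        sensitivity=op["sensitivity"],
        specificity=op["specificity"],
        accuracy=op["accuracy"],
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


@dataclass
class StabilityReport:
    auc_mean: float
    auc_sd: float
    rsd_percent: float

    def to_dict(self) -> dict:
        return {"auc_mean": self.auc_mean, "auc_sd": self.auc_sd, "rsd_percent": self.rsd_percent}


def rsd_stability(aucs) -> StabilityReport:
    """(sample SD of AUC / mean AUC) x 100."""
    a = np.asarray(aucs, dtype=np.float64)
    if a.size < 2:
        raise ValueError("need at least 2 AUC values")
    mean = a.mean()
    if mean <= 0:
        raise ValueError("mean AUC must be positive")
    sd = a.std(ddof=1)
    return StabilityReport(auc_mean=float(mean), auc_sd=float(sd), rsd_percent=float(100.0 * sd / mean))


def grid_heatmap_export(
    results: dict[tuple[str, str], dict[str, float]],
    selectors: list[str],
    classifiers: list[str],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Selector x classifier tables (one CSV per metric), Fig.-2 style."""
    missing = [(s, c) for s in selectors for c in classifiers if (s, c) not in results]
    if missing:
        raise ValueError(f"missing grid cell(s): {missing}")
    if len(selectors) * len(classifiers) != len(results):
        raise ValueError("results must contain exactly the selector x classifier grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for metric in ("auc", "rsd"):
        df = pd.DataFrame(
            [[results[(s, c)][metric] for c in classifiers] for s in selectors],
            index=selectors,
            columns=classifiers,
        )
        df.index.name = "selector"
        path = out_dir / f"grid_{metric}.csv"
        df.to_csv(path)
        paths[metric] = path
    return paths
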