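"""Multilayer-perceptron ensemble with class-weighted cross-entropy.

The classifier of Metric 2: fully connected nets whose hidden widths come
from a dash string ("100-10" = two hidden layers), ReLU activations and a
2-unit softmax output, trained by plain SGD with momentum 0.25, batch size
32 and learning rate 1e-3 without weight decay, minimising cross-entropy
with a class weight of 1.467 on the PCNSL terms to counter the 73:50 class
imbalance. Ten members — one per stratified 10-fold split, each trained on
the other 9 folds with that fold's standardisation statistics — form the
ensemble; the hard label is the majority vote (5-5 ties resolve by mean
probability) and the continuous score is the mean member PCNSL probability.

The trainer is hand-written in numpy so the loss weighting and the SGD
schedule match the stated hyper-parameters exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

#: the architecture sweep of the Methods section
DEFAULT_ARCHITECTURES = ("100-10", "500-100-10", "500-100-50-10", "500-250-100-50-20")


@dataclass(frozen=True)
class MLPArchitecture:
    """Hidden-layer widths parsed from a dash string; output layer implicit."""

    hidden: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.hidden) < 1 or any(w <= 0 for w in self.hidden):
            raise ValueError("need >= 1 positive hidden width")

    @classmethod
    def parse(cls, s: str) -> "MLPArchitecture":
        try:
            widths = tuple(int(w) for w in s.strip().split("-"))
        except ValueError as e:
            raise ValueError(f"bad architecture string {s!r}") from e
        return cls(widths)

    def __str__(self) -> str:
        return "-".join(str(w) for w in self.hidden)


@dataclass
class TrainingConfig:
    batch_size: int = 32
    momentum: float = 0.25
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    class_weight_pcnsl: float = 1.467
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0


class MLPNet:
    """ReLU MLP with 2-unit softmax head, trained by SGD(momentum)."""

    def __init__(self, arch: MLPArchitecture, n_inputs: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        sizes = [n_inputs, *arch.hidden, 2]
        self.W = [rng.normal(0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1])) for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X: np.ndarray):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if i == len(self.W) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return acts, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1]

    def loss(self, X: np.ndarray, y: np.ndarray, class_weights: np.ndarray) -> float:
        probs = self.predict_proba(X)
        w = class_weights[y]
        ll = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
        return float((w * ll).sum() / w.sum())

    def sgd_step(self, X: np.ndarray, y: np.ndarray, class_weights: np.ndarray, lr: float, momentum: float, velocity):
        acts, probs = self.forward(X)
        n = len(y)
        w = class_weights[y][:, None]
        delta = (probs - np.eye(2)[y]) * w / w.sum()
        grads_W, grads_b = [], []
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = acts[i]
            grads_W.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        grads_W.reverse()
        grads_b.reverse()
        vW, vb = velocity
        for i in range(len(self.W)):
            vW[i] = momentum * vW[i] - lr * grads_W[i]
            vb[i] = momentum * vb[i] - lr * grads_b[i]
            self.W[i] += vW[i]
            self.b[i] += vb[i]


def class_weight_vector(cfg: TrainingConfig) -> np.ndarray:
    """Per-class loss weights; class 1 = PCNSL gets cfg.class_weight_pcnsl."""
    return np.array([1.0, cfg.class_weight_pcnsl])


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    arch: MLPArchitecture,
    cfg: TrainingConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[MLPNet, list[float]]:
    """Train one member net; early stop on validation loss when provided."""
    rng = np.random.default_rng(seed)
    net = MLPNet(arch, X.shape[1], seed=int(rng.integers(2**31)))
    cw = class_weight_vector(cfg)
    velocity = ([np.zeros_like(W) for W in net.W], [np.zeros_like(b) for b in net.b])
    n = len(y)
    best_val = np.inf
    best_state = None
    stale = 0
    history: list[float] = []
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            net.sgd_step(X[idx], y[idx], cw, cfg.learning_rate, cfg.momentum, velocity)
        train_loss = net.loss(X, y, cw)
        if not np.isfinite(train_loss):
            raise FloatingPointError("training diverged (loss is not finite)")
        history.append(train_loss)
        if X_val is not None and len(y_val) > 0:
            val_loss = net.loss(X_val, y_val, cw)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = ([W.copy() for W in net.W], [b.copy() for b in net.b])
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        net.W, net.b = best_state
    return net, history


@dataclass
class EnsembleMember:
    net: MLPNet
    fold_index: int
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.scaler_mean) / self.scaler_sd
        return self.net.predict_proba(Xs)


@dataclass
class TrainedEnsemble:
    arch: MLPArchitecture
    members: list[EnsembleMember] = field(default_factory=list)
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.members and len(self.members) != len({m.fold_index for m in self.members}):
            raise ValueError("members must come from distinct folds")

    def member_probs(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict_proba(X)[:, 1] for m in self.members])  # (members, n)


def train_mlp_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    arch: MLPArchitecture | str,
    cfg: TrainingConfig = TrainingConfig(),
    n_folds: int = 10,
) -> TrainedEnsemble:
    """One member per stratified fold, trained on the other folds.

    Standardisation uses each member's training-fold statistics only; a
    divergent member raises with its fold id.
    """
    if isinstance(arch, str):
        arch = MLPArchitecture.parse(arch)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = np.asarray(X, dtype=np.float64)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
    members: list[EnsembleMember] = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (X[tr] - mu) / sd
        Xva = (X[va] - mu) / sd
        try:
            net, _ = train_mlp(Xtr, y[tr], arch, cfg, Xva, y[va], seed=cfg.seed * 1009 + fold)
        except FloatingPointError as e:
            raise FloatingPointError(f"member for fold {fold} diverged") from e
        members.append(EnsembleMember(net=net, fold_index=fold, scaler_mean=mu, scaler_sd=sd))
    return TrainedEnsemble(arch=arch, members=members)


def predict_ensemble(ens: TrainedEnsemble, X: np.ndarray) -> dict[str, np.ndarray]:
    """Majority-vote labels and mean-probability scores.

    5-5 vote ties resolve by mean PCNSL probability >= 0.5.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != ens.members[0].scaler_mean.shape[0]:
        raise ValueError("feature dimension mismatch with training")
    probs = ens.member_probs(X)  # (members, n)
    votes = (probs >= 0.5).sum(axis=0)
    score = probs.mean(axis=0)
    n_members = probs.shape[0]
    labels = np.where(
        votes * 2 == n_members,  # tie
        (score >= 0.5).astype(int),
        (votes * 2 > n_members).astype(int),
    )
    return {"label": labels, "score": score, "votes": votes}
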