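"""CNN-GRU Brunnstrom-stage classifier and its WOA hyperparameter search.

The decision model maps a W x 6 feature window to one of the stage
classes.  Architecture: two same-padded 1-D convolutions over time
(kernel 3, 16 then 32 filters, ReLU), each followed by a max-pool of 2;
the pooled sequence feeds a single-layer GRU whose final hidden state
goes through a linear head to per-class scores.  Training minimizes
softmax cross-entropy plus an L2 penalty on the weight matrices with
Adam (batch size 16).  Input channels are standardized with statistics
fitted on the training split only.

Three hyperparameters are searched by the whale optimization algorithm
over the box lr in [1e-4, 1e-1], hidden units in [10, 30], L2 in
[1e-5, 1e-2] (8 agents, 5 iterations); the fitness of a candidate is
its validation error rate after a reduced training budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .optimizers import OptimizerRun, WoaConfig, woa_optimize

HP_LOWER = np.array([1e-4, 10.0, 1e-5])  # (learning rate, hidden units, L2)
HP_UPPER = np.array([1e-1, 30.0, 1e-2])


@dataclass(frozen=True)
class Hyperparameters:
    hidden_units: int = 10
    learning_rate: float = 1e-3
    l2_coefficient: float = 5e-5

    def __post_init__(self) -> None:
        if not HP_LOWER[1] <= self.hidden_units <= HP_UPPER[1]:
            raise ValueError(f"hidden_units must lie in [{int(HP_LOWER[1])}, {int(HP_UPPER[1])}]")
        if not HP_LOWER[0] <= self.learning_rate <= HP_UPPER[0]:
            raise ValueError("learning_rate outside search bounds")
        if not HP_LOWER[2] <= self.l2_coefficient <= HP_UPPER[2]:
            raise ValueError("l2_coefficient outside search bounds")


#: Expert-experience control configuration used as the tuning baseline.
CONTROL_HP = Hyperparameters(hidden_units=10, learning_rate=1e-3, l2_coefficient=5e-5)


@dataclass(frozen=True)
class ModelSpec:
    n_channels: int = 6
    window: int = 50
    conv_filters: tuple[int, int] = (16, 32)
    kernel: int = 3
    n_classes: int = 5


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 600
    batch_size: int = 16
    seed: int = 0
    fitness_epochs: int = 60  # reduced budget used inside the WOA search

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.fitness_epochs <= 0:
            raise ValueError("epochs, batch_size and fitness_epochs must be > 0")


@dataclass
class DataSplits:
    """Train / validation / test window tensors and integer labels."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_valid: np.ndarray
    y_valid: np.ndarray
    X_test: np.ndarray | None = None
    y_test: np.ndarray | None = None


class CnnGruModel:
    """Parameter container with forward/backward passes; see module docs."""

    def __init__(self, spec: ModelSpec, hp: Hyperparameters, seed: int = 0):
        self.spec = spec
        self.hp = hp
        self.seed = seed
        self.scaler: tuple[np.ndarray, np.ndarray] | None = None
        rng = np.random.default_rng(seed)
        f1, f2 = spec.conv_filters
        K, C, H = spec.kernel, spec.n_channels, hp.hidden_units

        def uni(fan_in, *shape):
            k = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-k, k, size=shape)

        self.params: dict[str, np.ndarray] = {
            "W1": uni(K * C, f1, K * C), "b1": uni(K * C, f1),
            "W2": uni(K * f1, f2, K * f1), "b2": uni(K * f1, f2),
            "Wx": uni(H, f2, 3 * H), "Wh": uni(H, H, 3 * H),
            "bx": uni(H, 3 * H), "bh": uni(H, 3 * H),
            "Wo": uni(H, H, spec.n_classes), "bo": uni(H, spec.n_classes),
        }

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            return X
        mean, std = self.scaler
        return (X - mean) / std

    def fit_scaler(self, X: np.ndarray) -> None:
        mean = X.mean(axis=(0, 1))
        std = np.maximum(X.std(axis=(0, 1)), 1e-8)
        self.scaler = (mean, std)

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.spec.n_channels:
            raise ValueError(f"expected windows of shape (B, W, {self.spec.n_channels})")
        return X

    def forward(self, X: np.ndarray, want_cache: bool = False):
        p = self.params
        X = self._standardize(self._check_input(X))
        a1, col1 = nn.conv1d_forward(X, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        p1, mp1 = nn.maxpool2_forward(r1)
        a2, col2 = nn.conv1d_forward(p1, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        p2, mp2 = nn.maxpool2_forward(r2)
        h, gru_cache = nn.gru_forward(p2, p["Wx"], p["Wh"], p["bx"], p["bh"])
        logits = h @ p["Wo"] + p["bo"]
        if not want_cache:
            return logits, None
        return logits, (col1, a1, mp1, col2, a2, mp2, gru_cache, h)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        p = self.params
        logits, cache = self.forward(X, want_cache=True)
        col1, a1, mp1, col2, a2, mp2, gru_cache, h = cache
        loss, dlogits, _ = nn.softmax_cross_entropy(logits, y)

        grads = {"Wo": h.T @ dlogits, "bo": dlogits.sum(axis=0)}
        dh = dlogits @ p["Wo"].T
        dp2, grads["Wx"], grads["Wh"], grads["bx"], grads["bh"] = nn.gru_backward(
            dh, gru_cache, p["Wx"], p["Wh"])
        dr2 = nn.maxpool2_backward(dp2, mp2)
        da2 = dr2 * (a2 > 0)
        dp1, grads["W2"], grads["b2"] = nn.conv1d_backward(
            da2, col2, p["W2"], self.spec.conv_filters[0])
        dr1 = nn.maxpool2_backward(dp1, mp1)
        da1 = dr1 * (a1 > 0)
        _, grads["W1"], grads["b1"] = nn.conv1d_backward(
            da1, col1, p["W1"], self.spec.n_channels)

        l2 = self.hp.l2_coefficient
        for k in ("W1", "W2", "Wx", "Wh", "Wo"):
            loss += 0.5 * l2 * float(np.sum(p[k] ** 2))
            grads[k] = grads[k] + l2 * p[k]
        return loss, grads

    def weight_norm(self) -> float:
        return float(np.sqrt(sum(np.sum(self.params[k] ** 2)
                                 for k in ("W1", "W2", "Wx", "Wh", "Wo"))))


def build_model(spec: ModelSpec, hp: Hyperparameters, seed: int = 0) -> CnnGruModel:
    """Seeded model construction; identical (spec, hp, seed) give identical weights."""
    if spec.window < 4:
        raise ValueError("window must allow two poolings of 2 (>= 4 timesteps)")
    return CnnGruModel(spec, hp, seed)


def train(model: CnnGruModel, X_train: np.ndarray, y_train: np.ndarray,
          X_valid: np.ndarray | None = None, y_valid: np.ndarray | None = None,
          cfg: TrainConfig = TrainConfig(), epochs: int | None = None) -> dict:
    """Train in place with Adam; returns {'loss': per-epoch mean loss,
    'valid_accuracy': final validation accuracy or None}."""
    X_train = model._check_input(X_train)
    n = X_train.shape[0]
    if n == 0:
        raise ValueError("training set is empty")
    y_train = np.asarray(y_train, dtype=np.int64)
    if y_train.shape != (n,) or y_train.min() < 0 or y_train.max() >= model.spec.n_classes:
        raise ValueError("labels must be 1-D class indices matching the batch")

    if model.scaler is None:
        model.fit_scaler(X_train)
    n_epochs = epochs if epochs is not None else cfg.epochs
    rng = np.random.default_rng(cfg.seed)
    adam = nn.Adam(model.params, lr=model.hp.learning_rate)
    history = []
    for _ in range(n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx])
            adam.step(model.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))

    valid_acc = None
    if X_valid is not None and len(X_valid):
        labels, _ = predict(model, X_valid)
        valid_acc = float(np.mean(labels == np.asarray(y_valid)))
    return {"loss": history, "valid_accuracy": valid_acc}


def predict(model: CnnGruModel, X: np.ndarray, batch_size: int = 256):
    """Deterministic argmax prediction; returns (labels, softmax probabilities)."""
    X = model._check_input(X)
    probs = []
    for start in range(0, X.shape[0], batch_size):
        logits, _ = model.forward(X[start:start + batch_size])
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs.append(e / e.sum(axis=1, keepdims=True))
    probs = np.concatenate(probs) if probs else np.zeros((0, model.spec.n_classes))
    return probs.argmax(axis=1), probs


def decode_position(position: np.ndarray) -> Hyperparameters:
    """Map a WOA search point (lr, hidden, L2) to hyperparameters.

    Clipped into the search box; hidden units rounded to an integer.
    """
    pos = np.clip(np.asarray(position, dtype=float), HP_LOWER, HP_UPPER)
    return Hyperparameters(hidden_units=int(round(pos[1])),
                           learning_rate=float(pos[0]),
                           l2_coefficient=float(pos[2]))


def fitness_fobj(position: np.ndarray, splits: DataSplits,
                 cfg: TrainConfig, spec: ModelSpec = ModelSpec()) -> float:
    """WOA fitness: validation error rate after the reduced training budget."""
    hp = decode_position(position)
    model = build_model(spec, hp, seed=cfg.seed)
    result = train(model, splits.X_train, splits.y_train,
                   splits.X_valid, splits.y_valid, cfg=cfg, epochs=cfg.fitness_epochs)
    return 1.0 - result["valid_accuracy"]


def woa_tune(splits: DataSplits, woa_config: WoaConfig | None = None,
             train_cfg: TrainConfig = TrainConfig(),
             spec: ModelSpec = ModelSpec()) -> tuple[Hyperparameters, OptimizerRun]:
    """Search the 3-D hyperparameter box with WOA (8 agents, 5 iterations)."""
    cfg = woa_config or WoaConfig(seed=train_cfg.seed)
    if cfg.dim != 3:
        raise ValueError("hyperparameter search is 3-dimensional")
    run = woa_optimize(lambda pos: fitness_fobj(pos, splits, train_cfg, spec), cfg)
    return decode_position(run.best_pos), run
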