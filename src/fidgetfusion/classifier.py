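"""Training and application of the temporal CNN classifier.

One network per sensor modality (or one fused network): three 1-D
convolutional layers and one fully connected layer, each followed by
batch normalization and 20% dropout, ReLU activations, and a single
linear output unit whose logit feeds a binary cross-entropy loss. The
Adam optimizer (batch size 4, learning rate 0.001, beta1 0.9, beta2
0.999, epsilon 1e-07) is used with a validation stop: the last 1/8 of a
seeded shuffle of the training snippets is held out and training stops
once the validation loss has not improved for 10 epochs, returning the
weights of the best epoch. Model selection repeats training from random
initial conditions (20 restarts by default) and keeps the network with
the lowest validation loss.

The :class:`CNNSnippetClassifier` wraps this protocol as a scikit-learn
estimator over arrays of shape (n_snippets, frames, channels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .snippets import NormStats

__all__ = [
    "CNNConfig", "TrainConfig", "TrainedClassifier",
    "build_model", "train_model", "train_with_restarts",
    "predict_proba", "grid_search_light",
    "CNNSnippetClassifier", "save_classifier", "load_classifier",
]


class DataError(ValueError):
    """Raised when the training data cannot support the protocol."""


@dataclass(frozen=True)
class CNNConfig:
    """Architecture of one temporal CNN.

    ``conv_layers`` is a list of (n_kernels, kernel_size) pairs; the
    default interior (32, 64, 64 kernels of size 5; 64 FC units) is a sane
    mid-sized choice — the architecture search that produced per-modality
    optima is out of scope, so everything is configurable.
    """

    conv_layers: tuple = ((32, 5), (64, 5), (64, 5))
    fc_units: int = 64
    dropout_rate: float = 0.20
    batch_norm: bool = True
    input_shape: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "conv_layers",
                           tuple((int(n), int(k)) for n, k in self.conv_layers))
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for _, k in self.conv_layers:
            if k < 1:
                raise ValueError("kernel_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "conv_layers": [list(c) for c in self.conv_layers],
            "fc_units": self.fc_units,
            "dropout_rate": self.dropout_rate,
            "batch_norm": self.batch_norm,
            "input_shape": list(self.input_shape) if self.input_shape else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CNNConfig":
        return cls(
            conv_layers=tuple(tuple(c) for c in d["conv_layers"]),
            fc_units=int(d["fc_units"]),
            dropout_rate=float(d["dropout_rate"]),
            batch_norm=bool(d["batch_norm"]),
            input_shape=tuple(d["input_shape"]) if d.get("input_shape") else None,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol parameters (defaults follow the study protocol)."""

    batch_size: int = 4
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-07
    val_split: float = 1.0 / 8.0
    patience: int = 10
    max_epochs: int = 200
    n_restarts: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_split < 1.0:
            raise ValueError("val_split must be in (0, 1)")
        if self.patience < 1 or self.n_restarts < 1:
            raise ValueError("patience and n_restarts must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "batch_size", "learning_rate", "beta1", "beta2", "epsilon",
            "val_split", "patience", "max_epochs", "n_restarts", "seed")}


@dataclass
class TrainedClassifier:
    """A fitted network plus its provenance (config, log, best val loss)."""

    config: CNNConfig
    net: nn.SequentialNet
    training_log: list                 # (epoch, train_loss, val_loss) rows
    best_val_loss: float
    norm_stats: NormStats | None = None
    restart_index: int = 0


def build_model(config: CNNConfig, rng: np.random.Generator | None = None) -> nn.SequentialNet:
    """Instantiate an untrained network for ``config.input_shape``."""
    if config.input_shape is None:
        raise ValueError("config.input_shape must be set to build a model")
    frames, channels = config.input_shape
    rng = rng if rng is not None else np.random.default_rng(0)
    layers = []
    c_in = channels
    for n_kernels, ksize in config.conv_layers:
        if ksize > frames:
            raise ValueError(f"kernel size {ksize} exceeds {frames} input frames")
        layers.append(nn.Conv1D(c_in, n_kernels, ksize, rng))
        if config.batch_norm:
            layers.append(nn.BatchNorm(n_kernels))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_rate))
        c_in = n_kernels
    layers.append(nn.Flatten())
    layers.append(nn.Dense(frames * c_in, config.fc_units, rng))
    if config.batch_norm:
        layers.append(nn.BatchNorm(config.fc_units))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(config.dropout_rate))
    layers.append(nn.Dense(config.fc_units, 1, rng))
    return nn.SequentialNet(layers)


def _forward_loss(net, X, y, batch: int = 256) -> float:
    total, n = 0.0, len(y)
    for lo in range(0, n, batch):
        logits = net.forward(X[lo:lo + batch], training=False)
        loss, _ = nn.bce_with_logits(logits, y[lo:lo + batch])
        total += loss * len(y[lo:lo + batch])
    return total / n


def train_model(X: np.ndarray, y: np.ndarray, config: CNNConfig,
                tc: TrainConfig) -> TrainedClassifier:
    """Train one network with the validation-stop protocol.

    The last ``val_split`` fraction of a seeded shuffle of the snippets is
    held out for validation; training stops when the validation loss fails
    to improve for ``patience`` epochs (or at ``max_epochs``) and the
    weights of the best-validation-loss epoch are restored. Fully
    reproducible from ``tc.seed``.
    """
    X = np.asarray(X, dtype=nn.DTYPE)
    y = np.asarray(y, dtype=nn.DTYPE)
    if X.ndim != 3:
        raise ValueError("X must be (n_snippets, frames, channels)")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("training set contains a single class")
    if counts.min() < 2:
        raise DataError("need at least 2 snippets per class")

    rng = np.random.default_rng(tc.seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(tc.val_split * n)))
    val_idx, train_idx = perm[n - n_val:], perm[: n - n_val]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    cfg = replace(config, input_shape=(X.shape[1], X.shape[2]))
    net = build_model(cfg, rng)
    opt = nn.Adam(net.params(), tc.learning_rate, tc.beta1, tc.beta2, tc.epsilon)

    best_state, best_val, best_epoch = net.get_state(), np.inf, -1
    log = []
    since_improve = 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(ytr))
        epoch_loss, n_seen = 0.0, 0
        for lo in range(0, len(order), tc.batch_size):
            idx = order[lo:lo + tc.batch_size]
            logits = net.forward(Xtr[idx], training=True, rng=rng)
            loss, dlogits = nn.bce_with_logits(logits, ytr[idx])
            net.backward(dlogits)
            opt.step(net.grads())
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss = _forward_loss(net, Xval, yval)
        log.append((epoch, epoch_loss / n_seen, val_loss))
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = net.get_state()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= tc.patience:
                break
    net.set_state(best_state)
    return TrainedClassifier(config=cfg, net=net, training_log=log,
                             best_val_loss=float(best_val))


def _restart_seed(master_seed: int, restart: int) -> int:
    if restart == 0:
        return int(master_seed)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(restart,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def train_with_restarts(X: np.ndarray, y: np.ndarray, config: CNNConfig,
                        tc: TrainConfig) -> TrainedClassifier:
    """Run ``n_restarts`` independent trainings; keep the lowest val loss.

    Restart 0 uses ``tc.seed`` itself (so ``n_restarts=1`` reduces exactly
    to :func:`train_model`); later restarts use seeds derived
    deterministically from (seed, restart). Ties break toward the earliest
    restart.
    """
    best = None
    for r in range(tc.n_restarts):
        tc_r = replace(tc, seed=_restart_seed(tc.seed, r))
        cand = train_model(X, y, config, tc_r)
        cand.restart_index = r
        if best is None or cand.best_val_loss < best.best_val_loss:
            best = cand
    return best


def predict_proba(clf: TrainedClassifier, X: np.ndarray, batch: int = 256) -> np.ndarray:
    """FM+ probability (sigmoid of the logit) for each snippet in X.

    Inference is deterministic: dropout off, batch norm in inference mode.
    """
    X = np.asarray(X, dtype=nn.DTYPE)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1:] != tuple(clf.config.input_shape):
        raise ValueError(
            f"feature shape {X.shape[1:]} does not match model input "
            f"{tuple(clf.config.input_shape)}")
    probs = np.concatenate([
        nn.sigmoid(clf.net.forward(X[lo:lo + batch], training=False))
        for lo in range(0, len(X), batch)
    ])
    return probs[0] if single else probs


def grid_search_light(X: np.ndarray, y: np.ndarray, grid, tc: TrainConfig):
    """Train every config in *grid* with the validation stop and rank them.

    Returns ``[(config, best_val_loss), ...]`` sorted by ascending
    validation loss. This is a deliberately reduced search utility; the
    full two-stage architecture optimization is out of scope.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    scored = []
    for config in grid:
        fitted = train_with_restarts(X, y, config, tc)
        scored.append((config, fitted.best_val_loss))
    scored.sort(key=lambda pair: pair[1])
    return scored


class CNNSnippetClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator around the temporal CNN training protocol.

    Accepts X of shape (n_snippets, frames, channels) and binary labels
    (FM- = 0, FM+ = 1). ``fit`` runs ``n_restarts`` trainings with the
    validation stop and keeps the best network by validation loss.

    Examples
    --------
    >>> clf = CNNSnippetClassifier(conv_layers=((8, 5),) * 3, fc_units=16,
    ...                            n_restarts=1, max_epochs=5, random_state=0)
    >>> clf.fit(X_train, y_train).predict(X_test)        # doctest: +SKIP
    """

    def __init__(self, conv_layers=((32, 5), (64, 5), (64, 5)), fc_units=64,
                 dropout_rate=0.20, batch_norm=True, batch_size=4,
                 learning_rate=0.001, beta1=0.9, beta2=0.999, epsilon=1e-07,
                 val_split=1.0 / 8.0, patience=10, max_epochs=200,
                 n_restarts=20, random_state=0):
        self.conv_layers = conv_layers
        self.fc_units = fc_units
        self.dropout_rate = dropout_rate
        self.batch_norm = batch_norm
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.val_split = val_split
        self.patience = patience
        self.max_epochs = max_epochs
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _configs(self):
        cnn = CNNConfig(conv_layers=tuple(tuple(c) for c in self.conv_layers),
                        fc_units=self.fc_units, dropout_rate=self.dropout_rate,
                        batch_norm=self.batch_norm)
        tc = TrainConfig(batch_size=self.batch_size,
                         learning_rate=self.learning_rate, beta1=self.beta1,
                         beta2=self.beta2, epsilon=self.epsilon,
                         val_split=self.val_split, patience=self.patience,
                         max_epochs=self.max_epochs, n_restarts=self.n_restarts,
                         seed=self.random_state)
        return cnn, tc

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        cnn, tc = self._configs()
        self.model_ = train_with_restarts(X, y.astype(float), cnn, tc)
        self.best_val_loss_ = self.model_.best_val_loss
        self.training_log_ = self.model_.training_log
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=nn.DTYPE)
        return np.concatenate([
            self.model_.net.forward(X[lo:lo + 256], training=False)
            for lo in range(0, len(X), 256)
        ])

    def predict_proba(self, X):
        p = nn.sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def save_classifier(clf: TrainedClassifier, path,
                    train_config: TrainConfig | None = None) -> Path:
    """Save weights (.npz) plus a JSON sidecar with configs and the log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = clf.net.get_state()
    arrays = {f"w{i}": w for i, w in enumerate(state["weights"])}
    for i, (mean, var) in enumerate(state["running"]):
        arrays[f"bn{i}_mean"] = mean
        arrays[f"bn{i}_var"] = var
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": clf.config.to_dict(),
        "train_config": train_config.to_dict() if train_config else None,
        "best_val_loss": clf.best_val_loss,
        "restart_index": clf.restart_index,
        "training_log": clf.training_log,
        "n_weights": len(state["weights"]),
        "n_bn": len(state["running"]),
        "norm_stats": clf.norm_stats.to_dict() if clf.norm_stats else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_classifier(path) -> TrainedClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = CNNConfig.from_dict(sidecar["config"])
    net = build_model(config, np.random.default_rng(0))
    data = np.load(path.with_suffix(".npz"))
    state = {
        "weights": [data[f"w{i}"] for i in range(sidecar["n_weights"])],
        "running": [(data[f"bn{i}_mean"], data[f"bn{i}_var"])
                    for i in range(sidecar["n_bn"])],
    }
    net.set_state(state)
    stats = sidecar.get("norm_stats")
    return TrainedClassifier(
        config=config, net=net,
        training_log=[tuple(row) for row in sidecar["training_log"]],
        best_val_loss=float(sidecar["best_val_loss"]),
        norm_stats=NormStats.from_dict(stats) if stats else None,
        restart_index=int(sidecar["restart_index"]),
    )
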