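"""Feedforward relevance classifier: forward pass, MSE loss, mini-batch SGD.

The network maps a one-hot article vector x to a relevance likelihood
ŷ = f(x; Θ) ∈ [0, 1] through a chain of layers h = g(Wᵀx + b): by default two
hidden layers of 64 ReLU units and a single sigmoid output unit.  Training
minimizes per-sample squared error (y − ŷ)² with plain stochastic gradient
descent: gradients are averaged over each mini-batch (size 8 by default, the
last short batch averaged over its actual size) and parameters updated as
θ ← θ − α·∇θL with learning rate α = 0.01 over 30 epochs.  All randomness
(weight initialization, per-epoch shuffling) is seeded, so training is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

RELU = "relu"
SIGMOID = "sigmoid"


def _activate(name: str, z: np.ndarray) -> np.ndarray:
    if name == RELU:
        return np.maximum(0.0, z)
    if name == SIGMOID:
        return 1.0 / (1.0 + np.exp(-z))
    raise ConfigError(f"unknown activation: {name}")


def _activate_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == RELU:
        return (z > 0.0).astype(np.float64)
    if name == SIGMOID:
        return a * (1.0 - a)
    raise ConfigError(f"unknown activation: {name}")


@dataclass
class LayerParams:
    W: np.ndarray  # (inputs, units)
    b: np.ndarray  # (units,)
    activation: str

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[1] != self.b.shape[0]:
            raise ConfigError(
                f"inconsistent layer shapes: W {self.W.shape}, b {self.b.shape}"
            )


@dataclass
class MLPModel:
    """Layer parameters plus the input dimension and a model-version string."""

    layers: list[LayerParams]
    input_dim: int
    version: str = "untrained"

    def __post_init__(self) -> None:
        dim = self.input_dim
        for layer in self.layers:
            if layer.W.shape[0] != dim:
                raise ConfigError(
                    f"layer expects {layer.W.shape[0]} inputs, got {dim}"
                )
            dim = layer.W.shape[1]
        if self.layers:
            if self.layers[-1].activation != SIGMOID or self.layers[-1].W.shape[1] != 1:
                raise ConfigError("output layer must be a single sigmoid unit")

    def weight_fingerprint(self) -> str:
        h = hashlib.sha256()
        for layer in self.layers:
            h.update(np.ascontiguousarray(layer.W).tobytes())
            h.update(np.ascontiguousarray(layer.b).tobytes())
        return h.hexdigest()[:12]

    def to_payload(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "version": self.version,
            "layers": [
                {"W": layer.W.tolist(), "b": layer.b.tolist(), "activation": layer.activation}
                for layer in self.layers
            ],
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "MLPModel":
        layers = [
            LayerParams(
                W=np.array(item["W"], dtype=np.float64),
                b=np.array(item["b"], dtype=np.float64),
                activation=item["activation"],
            )
            for item in payload["layers"]
        ]
        return cls(layers=layers, input_dim=int(payload["input_dim"]),
                   version=str(payload["version"]))


@dataclass
class TrainConfig:
    """SGD hyper-parameters (defaults are the tool's operating values)."""

    learning_rate: float = 0.01
    batch_size: int = 8
    epochs: int = 30
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if self.loss != "mse":
            raise ConfigError(f"unsupported loss: {self.loss}")


def build_mlp(
    input_dim: int, hidden_units: int = 64, hidden_layers: int = 2, seed: int = 0
) -> MLPModel:
    """Seeded small-scale symmetric initialization, U(−1/√fan_in, 1/√fan_in)."""
    if input_dim < 1:
        raise ConfigError("input_dim must be >= 1")
    rng = np.random.default_rng([seed, 1])
    dims = [input_dim] + [hidden_units] * hidden_layers + [1]
    activations = [RELU] * hidden_layers + [SIGMOID]
    layers = []
    for fan_in, fan_out, act in zip(dims[:-1], dims[1:], activations):
        scale = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-scale, scale, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        layers.append(LayerParams(W=W, b=b, activation=act))
    return MLPModel(layers=layers, input_dim=input_dim)


def _forward_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    a = X
    for layer in model.layers:
        a = _activate(layer.activation, a @ layer.W + layer.b)
    return a[:, 0]


def forward(model: MLPModel, x: np.ndarray) -> float:
    """Likelihood of relevance for one encoded article."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.input_dim,):
        raise ConfigError(
            f"input has shape {x.shape}, model expects ({model.input_dim},)"
        )
    return float(_forward_batch(model, x[None, :])[0])


def mse_loss(y_hat, y) -> float:
    """Per-sample squared error (y − ŷ)²; mean over a batch."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean((y - y_hat) ** 2))


def _backward_batch(model: MLPModel, X: np.ndarray, y: np.ndarray):
    """Gradients of the batch-mean squared error w.r.t. every W and b."""
    n = X.shape[0]
    a = X
    inputs, zs, acts = [], [], []
    for layer in model.layers:
        inputs.append(a)
        z = a @ layer.W + layer.b
        a = _activate(layer.activation, z)
        zs.append(z)
        acts.append(a)
    y_hat = acts[-1][:, 0]
    # d(mean (y-ŷ)²)/dŷ = 2(ŷ-y)/n
    delta = (2.0 * (y_hat - y) / n)[:, None]
    grads = [None] * len(model.layers)
    for i in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[i]
        delta = delta * _activate_grad(layer.activation, zs[i], acts[i])
        grads[i] = (inputs[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = delta @ layer.W.T
    return grads, y_hat


def train(
    model: MLPModel, X: np.ndarray, y: np.ndarray, config: TrainConfig
) -> tuple[MLPModel, list[dict]]:
    """Mini-batch SGD in place; returns the model and per-epoch history.

    Each epoch reshuffles (seeded), partitions into batches of
    ``config.batch_size`` (last batch may be smaller and is used, averaged
    over its actual size), and applies θ ← θ − α·grad.  History records the
    training-split loss and accuracy computed after each epoch's updates.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigError("training set is empty")
    if X.shape[1] != model.input_dim:
        raise ConfigError(
            f"training data has {X.shape[1]} features, model expects {model.input_dim}"
        )
    if y.shape != (X.shape[0],):
        raise ConfigError("labels must be a vector matching the number of samples")
    rng = np.random.default_rng([config.seed, 2])
    n = X.shape[0]
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grads, _ = _backward_batch(model, X[idx], y[idx])
            for layer, (gW, gb) in zip(model.layers, grads):
                layer.W -= config.learning_rate * gW
                layer.b -= config.learning_rate * gb
        y_hat = _forward_batch(model, X)
        history.append(
            {
                "epoch": epoch + 1,
                "loss": mse_loss(y_hat, y),
                "accuracy": float(np.mean((y_hat >= 0.5) == (y == 1.0))),
            }
        )
    if config.epochs > 0:
        model.version = f"m-{model.weight_fingerprint()}"
    return model, history


@dataclass
class ConfusionMatrix:
    """Binary counts with relevant as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if cm.total == 0:
        raise ConfigError("accuracy undefined for an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


@dataclass
class Metrics:
    accuracy: float
    loss: float


def evaluate(
    model: MLPModel, X: np.ndarray, y: np.ndarray
) -> tuple[ConfusionMatrix, Metrics, list[list[float]]]:
    """Score a held-out set: prediction = 1 iff likelihood ≥ 0.5.

    Returns the confusion matrix, accuracy + mean loss, and the per-sample
    ``[true value, classification value]`` pairs (likelihoods, not the
    thresholded predictions, so downstream triage can re-band them).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigError("test set is empty")
    y_hat = _forward_batch(model, X)
    pred = y_hat >= 0.5
    true = y == 1.0
    cm = ConfusionMatrix(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )
    metrics = Metrics(accuracy=accuracy(cm), loss=mse_loss(y_hat, y))
    per_sample = [[float(t), float(p)] for t, p in zip(y, y_hat)]
    return cm, metrics, per_sample


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    fold_indices: list[np.ndarray],
    config: TrainConfig,
    hidden_units: int = 64,
    hidden_layers: int = 2,
) -> list[Metrics]:
    """k-fold CV: train on k−1 folds, validate on the held-out fold."""
    results = []
    all_idx = [np.asarray(f, dtype=int) for f in fold_indices]
    for i, val_idx in enumerate(all_idx):
        train_idx = np.concatenate([f for j, f in enumerate(all_idx) if j != i])
        fold_model = build_mlp(
            X.shape[1], hidden_units=hidden_units, hidden_layers=hidden_layers,
            seed=config.seed + i,
        )
        train(fold_model, X[train_idx], y[train_idx], config)
        _, metrics, _ = evaluate(fold_model, X[val_idx], y[val_idx])
        results.append(metrics)
    return results
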