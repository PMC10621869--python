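"""Multilayer perceptron trained by backpropagation with the Adam optimizer.

The network is a small feed-forward classifier (default 15 -> 32 -> 2, tanh
hidden activation, softmax output, cross-entropy loss) written directly in
NumPy so the optimizer recursion is explicit.  Adam keeps exponentially
weighted first moments (V, momentum-like) and second moments (S, RMSProp-like)
of the gradients:

    S <- beta2*S + (1-beta2)*g^2        V <- beta1*V + (1-beta1)*g
    S_hat = S / (1-beta2^t)             V_hat = V / (1-beta1^t)
    w <- w - alpha * V_hat / (sqrt(S_hat) + eps)

with defaults alpha=0.01, beta1=0.9, beta2=0.999, eps=1e-8 and all moments
initialized to zero.  A ``literal_bias_correction`` flag switches to a variant
that divides the moments by (1-beta) without the step exponent and derives the
corrected first moment from S; it exists only for side-by-side comparison and
is not the default (that recursion is internally inconsistent as a first-moment
estimate).

Features are z-scored with training-split statistics before training; the
standardizer is stored on the model so prediction applies the same transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MlpConfig", "MlpModel", "AdamState", "adam_step",
           "forward", "predict", "predict_proba", "train"]


@dataclass
class MlpConfig:
    hidden_sizes: tuple[int, ...] = (32,)
    activation: str = "tanh"
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    literal_bias_correction: bool = False
    standardize: bool = True


_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(float)),
}


@dataclass
class MlpModel:
    """Weights W, biases b and the input standardizer of a trained network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MlpConfig
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    classes: list = field(default_factory=lambda: [0, 1])

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def save(self, path: str | Path) -> None:
        blob = {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "config": self.config.__dict__ | {
                "hidden_sizes": list(self.config.hidden_sizes)},
            "feature_mean": None if self.feature_mean is None
                            else self.feature_mean.tolist(),
            "feature_std": None if self.feature_std is None
                           else self.feature_std.tolist(),
            "classes": list(self.classes),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "MlpModel":
        blob = json.loads(Path(path).read_text())
        cfg_d = dict(blob["config"])
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        return cls(
            weights=[np.asarray(w) for w in blob["weights"]],
            biases=[np.asarray(b) for b in blob["biases"]],
            config=MlpConfig(**cfg_d),
            feature_mean=None if blob["feature_mean"] is None
                         else np.asarray(blob["feature_mean"]),
            feature_std=None if blob["feature_std"] is None
                        else np.asarray(blob["feature_std"]),
            classes=blob["classes"],
        )


@dataclass
class AdamState:
    """First (V) and second (S) moment accumulators, one per parameter tensor."""

    V_dw: list[np.ndarray]
    V_db: list[np.ndarray]
    S_dw: list[np.ndarray]
    S_db: list[np.ndarray]
    t: int = 0

    @classmethod
    def zeros_like(cls, model: MlpModel) -> "AdamState":
        return cls(V_dw=[np.zeros_like(w) for w in model.weights],
                   V_db=[np.zeros_like(b) for b in model.biases],
                   S_dw=[np.zeros_like(w) for w in model.weights],
                   S_db=[np.zeros_like(b) for b in model.biases])


def _init_model(n_features: int, config: MlpConfig, classes: list,
                rng: np.random.Generator) -> MlpModel:
    sizes = [n_features, *config.hidden_sizes, len(classes)]
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        # Glorot-uniform initialization
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        biases.append(np.zeros(n_out))
    return MlpModel(weights=weights, biases=biases, config=config,
                    classes=list(classes))


def _standardize(model: MlpModel, X: np.ndarray) -> np.ndarray:
    if model.feature_mean is None:
        return X
    return (X - model.feature_mean) / model.feature_std


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: MlpModel, X: np.ndarray,
            return_cache: bool = False):
    """Class probabilities for a batch; softmax output sums to 1 per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(f"feature dimension {X.shape[1]} does not match "
                         f"input layer {model.weights[0].shape[0]}")
    act, _ = _ACTIVATIONS[model.config.activation]
    a = _standardize(model, X)
    cache = [a]
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        a = _softmax(z) if i == n_layers - 1 else act(z)
        cache.append(a)
    return (a, cache) if return_cache else a


def _backward(model: MlpModel, cache: list[np.ndarray],
              y_onehot: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Cross-entropy gradients w.r.t. every W and b (mean over the batch)."""
    _, dact = _ACTIVATIONS[model.config.activation]
    n = y_onehot.shape[0]
    delta = (cache[-1] - y_onehot) / n          # softmax + CE shortcut
    dw, db = [], []
    for i in range(len(model.weights) - 1, -1, -1):
        dw.insert(0, cache[i].T @ delta)
        db.insert(0, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ model.weights[i].T) * dact(cache[i])
    return dw, db


def adam_step(model: MlpModel, grads: tuple[list[np.ndarray], list[np.ndarray]],
              state: AdamState) -> None:
    """One Adam update of all parameters, in place.

    Moment updates, bias correction and the parameter step follow the standard
    recursion; the literal variant (config flag) divides by (1-beta) without
    the step exponent and feeds S into the corrected first moment.
    """
    dw, db = grads
    for g in (*dw, *db):
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite gradient passed to adam_step")
    cfg = model.config
    state.t += 1
    b1, b2, eps, lr = cfg.beta1, cfg.beta2, cfg.eps, cfg.learning_rate
    for params, grads_l, V, S in ((model.weights, dw, state.V_dw, state.S_dw),
                                  (model.biases, db, state.V_db, state.S_db)):
        for p, g, v, s in zip(params, grads_l, V, S):
            s *= b2
            s += (1 - b2) * g**2
            v *= b1
            v += (1 - b1) * g
            if cfg.literal_bias_correction:
                s_hat = s / (1 - b2)
                v_hat = s / (1 - b1)
            else:
                s_hat = s / (1 - b2**state.t)
                v_hat = v / (1 - b1**state.t)
            p -= lr * v_hat / (np.sqrt(s_hat) + eps)


def _cross_entropy(proba: np.ndarray, y_idx: np.ndarray) -> float:
    p = np.clip(proba[np.arange(len(y_idx)), y_idx], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def train(X: np.ndarray, y, config: MlpConfig | None = None
          ) -> tuple[MlpModel, list[float]]:
    """Train an MLP with mini-batch Adam; returns the model and per-epoch loss.

    Deterministic given ``config.seed`` (initialization and batch shuffling
    both derive from it).  Raises if fewer than two classes are present.
    """
    if config is None:
        config = MlpConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError(f"need >=2 classes to train, got {classes}")
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.asarray([class_index[c] for c in y])
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    rng = np.random.default_rng(config.seed)
    model = _init_model(X.shape[1], config, classes, rng)
    if config.standardize:
        model.feature_mean = X.mean(axis=0)
        std = X.std(axis=0)
        model.feature_std = np.where(std > 0, std, 1.0)
    state = AdamState.zeros_like(model)
    y_onehot = np.eye(len(classes))[y_idx]

    n = len(X)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            _, cache = forward(model, X[idx], return_cache=True)
            grads = _backward(model, cache, y_onehot[idx])
            adam_step(model, grads, state)
        history.append(_cross_entropy(forward(model, X), y_idx))
    return model, history


def predict_proba(model: MlpModel, X: np.ndarray) -> np.ndarray:
    return forward(model, X)


def predict(model: MlpModel, X: np.ndarray) -> np.ndarray:
    """Class labels by score argmax; ties break toward the first class."""
    proba = forward(model, X)
    return np.asarray(model.classes)[np.argmax(proba, axis=1)]
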