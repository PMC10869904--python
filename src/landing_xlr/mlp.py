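"""Transparent feed-forward classifier with exposed per-layer traces.

A deliberately small, dependency-light dense network: tanh (or rectifier)
hidden layers, a linear 2-unit output read through softmax cross-entropy,
full-batch gradient descent with early stopping on a validation fold.
Every weight, bias, pre-activation and activation is exposed so relevance
propagation can walk the exact computation graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tasks import FoldPlan, TaskMatrix, zeror_baseline
from .synth import CLASS_ORDER

ACTIVATIONS = ("tanh", "rectifier", "identity")


class TrainingError(RuntimeError):
    """Raised when optimization produces non-finite loss or weights."""


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "rectifier":
        return np.maximum(z, 0.0)
    if name == "identity":
        return z
    raise ValueError(f"unknown activation: {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return 1.0 - a * a
    if name == "rectifier":
        return (z > 0.0).astype(z.dtype)
    if name == "identity":
        return np.ones_like(z)
    raise ValueError(f"unknown activation: {name!r}")


@dataclass
class DenseLayer:
    W: np.ndarray  # (fan_in, fan_out)
    b: np.ndarray  # (fan_out,)
    activation: str

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation: {self.activation!r}")
        if self.W.shape[1] != self.b.shape[0]:
            raise ValueError("bias length must equal layer width")


@dataclass
class NetworkModel:
    """Layered dense network; last layer is the linear class-score layer."""

    layers: list[DenseLayer]
    classes: tuple[str, ...] = CLASS_ORDER
    feature_mean: np.ndarray | None = None  # optional train-fold z-scoring
    feature_scale: np.ndarray | None = None

    @property
    def input_dim(self) -> int:
        return self.layers[0].W.shape[0]

    @property
    def n_classes(self) -> int:
        return self.layers[-1].W.shape[1]

    def preprocess(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {X.shape[1]} != model input {self.input_dim}"
            )
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        return X


@dataclass
class ForwardTrace:
    """Full forward pass record for a batch of inputs."""

    inputs: list[np.ndarray]  # activations entering each layer; inputs[0] = x
    preactivations: list[np.ndarray]  # z per layer
    scores: np.ndarray  # output-layer scores (n, n_classes)

    @property
    def predicted(self) -> np.ndarray:
        return self.scores.argmax(axis=1)


def forward(model: NetworkModel, X: np.ndarray) -> ForwardTrace:
    """Feed-forward evaluation, recording every intermediate tensor."""
    a = model.preprocess(X)
    inputs: list[np.ndarray] = []
    preacts: list[np.ndarray] = []
    for layer in model.layers:
        inputs.append(a)
        z = a @ layer.W + layer.b
        preacts.append(z)
        a = _act(layer.activation, z)
    return ForwardTrace(inputs=inputs, preactivations=preacts, scores=a)


def predict(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    trace = forward(model, X)
    return np.asarray([model.classes[i] for i in trace.predicted], dtype=object)


@dataclass(frozen=True)
class Hyperparams:
    """Training settings.

    ``preprocess`` is fit on the train folds only: ``none`` (default; raw
    features), ``center`` (subtract the train mean), or ``standardize``
    (z-score). Centering keeps low-variance channels at their natural
    scale, which matters when most features are uninformative.
    """

    hidden_units: int = 64
    hidden_activation: str = "tanh"
    learning_rate: float = 0.05
    max_epochs: int = 2000
    patience: int = 50
    l2: float = 1e-4
    preprocess: str = "none"
    init_scale: float = 1.0  # multiplier on the 1/sqrt(fan_in) uniform bound

    def __post_init__(self) -> None:
        if self.preprocess not in ("none", "center", "standardize"):
            raise ValueError(f"unknown preprocess mode: {self.preprocess!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(scores: np.ndarray, y_onehot: np.ndarray) -> float:
    p = _softmax(scores)
    return float(-(y_onehot * np.log(np.clip(p, 1e-12, None))).sum() / len(scores))


def _init_layers(
    dims: list[int], activation: str, init_scale: float, rng: np.random.Generator
) -> list[DenseLayer]:
    layers = []
    for li in range(len(dims) - 1):
        fan_in, fan_out = dims[li], dims[li + 1]
        bound = init_scale / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        act = activation if li < len(dims) - 2 else "identity"
        layers.append(DenseLayer(W=W, b=b, activation=act))
    return layers


def fit_network(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hyperparams: Hyperparams,
    seed: int,
    classes: tuple[str, ...] = CLASS_ORDER,
) -> NetworkModel:
    """Train on the train split with early stopping on validation cross-entropy.

    The test fold is never seen here: the returned weights are a
    deterministic function of (train, validation, hyperparams, seed) only.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    rng = np.random.default_rng(seed)

    mean = scale = None
    if hyperparams.preprocess != "none":
        mean = X_train.mean(axis=0)
        if hyperparams.preprocess == "standardize":
            scale = X_train.std(axis=0)
            scale = np.where(scale < 1e-12, 1.0, scale)
        else:  # center
            scale = np.ones_like(mean)
        X_train = (X_train - mean) / scale
        X_val = (X_val - mean) / scale

    label_to_idx = {c: i for i, c in enumerate(classes)}
    yt = np.asarray([label_to_idx[l] for l in y_train])
    yv = np.asarray([label_to_idx[l] for l in y_val])
    onehot_t = np.eye(len(classes))[yt]
    onehot_v = np.eye(len(classes))[yv]

    n_features = X_train.shape[1]
    hidden = min(hyperparams.hidden_units, n_features)
    dims = [n_features, hidden, len(classes)]
    layers = _init_layers(dims, hyperparams.hidden_activation, hyperparams.init_scale, rng)
    model = NetworkModel(layers=layers, classes=classes, feature_mean=mean, feature_scale=scale)

    best_val = np.inf
    best_weights = [(l.W.copy(), l.b.copy()) for l in layers]
    stale = 0
    n = len(X_train)
    lr = hyperparams.learning_rate

    for epoch in range(hyperparams.max_epochs):
        # forward
        acts = [X_train]
        zs = []
        a = X_train
        with np.errstate(over="ignore", invalid="ignore"):
            for layer in layers:
                z = a @ layer.W + layer.b
                a = _act(layer.activation, z)
                zs.append(z)
                acts.append(a)
        if not np.isfinite(a).all():
            raise TrainingError(f"non-finite scores at epoch {epoch}")
        # backward (softmax cross-entropy on linear output scores)
        with np.errstate(over="ignore", invalid="ignore"):
            delta = (_softmax(a) - onehot_t) / n
            for li in range(len(layers) - 1, -1, -1):
                layer = layers[li]
                if li < len(layers) - 1:
                    delta = delta * _act_grad(layer.activation, zs[li], acts[li + 1])
                gW = acts[li].T @ delta + hyperparams.l2 * layer.W
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ layer.W.T
                layer.W -= lr * gW
                layer.b -= lr * gb
        if any(not np.isfinite(l.W).all() for l in layers):
            raise TrainingError(f"non-finite weights at epoch {epoch}; reduce learning rate")
        # early stopping on validation cross-entropy
        with np.errstate(over="ignore", invalid="ignore"):
            val_ce = _cross_entropy(forward(model, X_val).scores, onehot_v)
        if val_ce < best_val - 1e-7:
            best_val = val_ce
            best_weights = [(l.W.copy(), l.b.copy()) for l in layers]
            stale = 0
        else:
            stale += 1
            if stale >= hyperparams.patience:
                break

    for layer, (W, b) in zip(layers, best_weights):
        layer.W = W
        layer.b = b
    return model


def train_mlp(
    task: TaskMatrix,
    fold_plan: FoldPlan,
    rotation: int,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> NetworkModel:
    """Train the network for one cross-validation rotation."""
    hyperparams = hyperparams or Hyperparams()
    train_m, val_m, _ = fold_plan.trial_masks(task.groups, rotation)
    return fit_network(
        task.X[train_m], task.y[train_m], task.X[val_m], task.y[val_m], hyperparams, seed
    )


@dataclass
class CvReport:
    task: str
    accuracies: np.ndarray  # per rotation
    zeror: np.ndarray  # per rotation
    mean: float = field(init=False)
    sd: float = field(init=False)
    zeror_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        self.zeror = np.asarray(self.zeror, dtype=float)
        self.mean = float(self.accuracies.mean())
        # sample SD over the k rotations (0 when k == 1)
        self.sd = float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0
        self.zeror_mean = float(self.zeror.mean())

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "accuracies": self.accuracies.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "zeror": self.zeror.tolist(),
            "zeror_mean": self.zeror_mean,
        }


def evaluate_cv(
    task: TaskMatrix,
    fold_plan: FoldPlan,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    return_models: bool = False,
):
    """Run all k rotations; returns a CvReport (and the per-rotation models).

    Per-rotation seeds are spawned from ``seed`` so each rotation is
    independently reproducible. The Zero-R baseline uses the majority class
    of the 6 training folds of the same rotation.
    """
    hyperparams = hyperparams or Hyperparams()
    child_seeds = np.random.SeedSequence(seed).generate_state(fold_plan.k)
    accs, zrbs, models = [], [], {}
    for r in range(fold_plan.k):
        train_m, val_m, test_m = fold_plan.trial_masks(task.groups, r)
        try:
            model = fit_network(
                task.X[train_m],
                task.y[train_m],
                task.X[val_m],
                task.y[val_m],
                hyperparams,
                int(child_seeds[r]),
            )
        except TrainingError as exc:
            raise TrainingError(f"rotation {r}: {exc}") from exc
        y_hat = predict(model, task.X[test_m])
        accs.append(float(np.mean(y_hat == task.y[test_m])))
        zrbs.append(zeror_baseline(task.y[train_m], task.y[test_m]))
        if return_models:
            models[r] = model
    report = CvReport(task=task.task, accuracies=np.asarray(accs), zeror=np.asarray(zrbs))
    return (report, models) if return_models else report
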