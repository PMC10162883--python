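"""From-scratch feedforward backpropagation regression network.

Architecture: 5 inputs -> 40 tanh hidden units -> 1 linear output.  Each
neuron computes ``y = sum_i x_i * w_i + b``; hidden activations are the
hyperbolic tangent, the output neuron is identity (regression).  Inputs and
targets are min-max scaled to [-1, 1] with parameters fitted on the
training split only.  Training is full-batch gradient descent on the mean
squared error in scaled space, with early stopping on validation MSE and
restoration of the best-validation weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateDataError,
    ParameterError,
    SchemaError,
    TrainingDivergedError,
)

N_INPUTS = 5
N_HIDDEN = 40


def tanh_activation(x):
    """Tan-sigmoid activation: odd, saturating at +/-1."""
    return np.tanh(x)


@dataclass
class AffineScaling:
    """Per-column min-max map onto [-1, 1] with exact inverse.

    Zero-range columns map to 0 and invert back to their constant value.
    """

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        self.lo = np.atleast_1d(np.asarray(self.lo, dtype=float))
        self.hi = np.atleast_1d(np.asarray(self.hi, dtype=float))
        if self.lo.shape != self.hi.shape:
            raise ParameterError("scaling lo/hi shape mismatch")

    @classmethod
    def fit(cls, X: np.ndarray) -> "AffineScaling":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.hi - self.lo
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (X - self.lo) / safe - 1.0
        return np.where(span == 0, 0.0, out)

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        span = self.hi - self.lo
        out = (Xs + 1.0) / 2.0 * span + self.lo
        return np.where(span == 0, self.lo, out)

    def to_dict(self) -> dict:
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, obj: dict) -> "AffineScaling":
        return cls(lo=np.array(obj["lo"]), hi=np.array(obj["hi"]))


@dataclass
class TrainingConfig:
    """Hyperparameters of the batch gradient-descent trainer."""

    learning_rate: float = 0.19
    max_epochs: int = 3000
    val_patience: int = 50
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ParameterError("split fractions must sum to 1")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be >= 1")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "val_patience": self.val_patience,
            "split_fractions": list(self.split_fractions),
            "seed": self.seed,
        }


@dataclass
class TrainingRecord:
    """Per-epoch loss curves and the stopping outcome."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1

    @property
    def epochs_run(self) -> int:
        return len(self.train_mse)


@dataclass
class BMDNetwork:
    """Weights, biases and scaling maps of the 5-40-1 regression network."""

    W1: np.ndarray  # (N_HIDDEN, N_INPUTS)
    b1: np.ndarray  # (N_HIDDEN,)
    W2: np.ndarray  # (N_HIDDEN,)
    b2: float
    input_scaling: AffineScaling
    target_scaling: AffineScaling
    rng_seed: int = 0
    n_inputs: int = N_INPUTS
    n_hidden: int = N_HIDDEN

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float).reshape(-1)
        self.b2 = float(self.b2)
        if self.W1.shape != (self.n_hidden, self.n_inputs):
            raise ParameterError(f"W1 must be {(self.n_hidden, self.n_inputs)}, got {self.W1.shape}")
        if self.b1.shape != (self.n_hidden,) or self.W2.shape != (self.n_hidden,):
            raise ParameterError("b1/W2 shape mismatch with hidden layer size")

    # -- forward ---------------------------------------------------------

    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """Scaled inputs -> scaled outputs, no scaling applied."""
        Xs = np.atleast_2d(Xs)
        H = tanh_activation(Xs @ self.W1.T + self.b1)
        return H @ self.W2 + self.b2

    def forward(self, features) -> float:
        """Predict BMD for a single feature vector (unscaled units in and out)."""
        x = _feature_row(features, self.n_inputs)
        if not np.all(np.isfinite(x)):
            raise ParameterError("non-finite feature value")
        ys = self.forward_scaled(self.input_scaling.transform(x[None, :]))
        return float(self.target_scaling.inverse(ys)[0])

    # -- persistence -----------------------------------------------------

    def to_json(self, path: str | Path, config: TrainingConfig | None = None) -> None:
        obj = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "input_scaling": self.input_scaling.to_dict(),
            "target_scaling": self.target_scaling.to_dict(),
            "seed": self.rng_seed,
            "n_inputs": self.n_inputs,
            "n_hidden": self.n_hidden,
        }
        if config is not None:
            obj["config"] = config.to_dict()
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "BMDNetwork":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            W1=np.array(obj["W1"]),
            b1=np.array(obj["b1"]),
            W2=np.array(obj["W2"]),
            b2=obj["b2"],
            input_scaling=AffineScaling.from_dict(obj["input_scaling"]),
            target_scaling=AffineScaling.from_dict(obj["target_scaling"]),
            rng_seed=int(obj.get("seed", 0)),
            n_inputs=int(obj.get("n_inputs", N_INPUTS)),
            n_hidden=int(obj.get("n_hidden", N_HIDDEN)),
        )


def init_network(
    seed: int,
    n_inputs: int = N_INPUTS,
    n_hidden: int = N_HIDDEN,
    input_scaling: AffineScaling | None = None,
    target_scaling: AffineScaling | None = None,
) -> BMDNetwork:
    """Seeded uniform initialization on [-1/sqrt(fan_in), +1/sqrt(fan_in)]."""
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(n_inputs)
    lim2 = 1.0 / np.sqrt(n_hidden)
    identity = AffineScaling(lo=-np.ones(1), hi=np.ones(1))
    return BMDNetwork(
        W1=rng.uniform(-lim1, lim1, size=(n_hidden, n_inputs)),
        b1=rng.uniform(-lim1, lim1, size=n_hidden),
        W2=rng.uniform(-lim2, lim2, size=n_hidden),
        b2=rng.uniform(-lim2, lim2),
        input_scaling=input_scaling
        or AffineScaling(lo=-np.ones(n_inputs), hi=np.ones(n_inputs)),
        target_scaling=target_scaling or identity,
        rng_seed=seed,
        n_inputs=n_inputs,
        n_hidden=n_hidden,
    )


# -- metrics -------------------------------------------------------------


def mse(pred, target) -> float:
    """Mean squared error between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.size == 0 or pred.size != target.size:
        raise SchemaError(f"length mismatch: {pred.size} vs {target.size}")
    return float(np.mean((pred - target) ** 2))


def correlation_coefficient(pred, target) -> float:
    """Pearson product-moment correlation R."""
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.size != target.size or pred.size < 2:
        raise SchemaError("need two equal-length vectors of length >= 2")
    if np.std(pred) == 0 or np.std(target) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float(np.corrcoef(pred, target)[0, 1])


# -- training ------------------------------------------------------------


def split_dataset(n_or_rows, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Random disjoint train/validation/test index partition.

    Sizes are ``round(f_train * n)`` and ``round(f_val * n)`` (half rounds
    up, favoring the training split) with the remainder as test.
    Deterministic for a fixed seed.
    """
    n = n_or_rows if isinstance(n_or_rows, (int, np.integer)) else len(n_or_rows)
    if n < 3:
        raise ParameterError(f"need at least 3 rows to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    n_train = int(np.floor(fractions[0] * n + 0.5))
    n_val = int(np.floor(fractions[1] * n + 0.5))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def loss_and_gradients(net: BMDNetwork, Xs: np.ndarray, ts: np.ndarray):
    """MSE loss in scaled space and its analytic gradients.

    Returns ``(loss, dW1, db1, dW2, db2)``.  Exposed separately so gradient
    checks can compare against finite differences.
    """
    Xs = np.atleast_2d(Xs)
    ts = np.asarray(ts, dtype=float).ravel()
    n = Xs.shape[0]
    A = Xs @ net.W1.T + net.b1  # (n, hidden) pre-activations
    H = tanh_activation(A)
    pred = H @ net.W2 + net.b2
    e = pred - ts
    loss = float(np.mean(e * e))
    dpred = 2.0 * e / n
    dW2 = dpred @ H
    db2 = float(dpred.sum())
    dH = np.outer(dpred, net.W2) * (1.0 - H * H)
    dW1 = dH.T @ Xs
    db1 = dH.sum(axis=0)
    return loss, dW1, db1, dW2, db2


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
    n_hidden: int = N_HIDDEN,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
):
    """Train the network with batch gradient descent and early stopping.

    ``X`` is (n, n_features), ``y`` is (n,) of BMD targets.  The data is
    split 70/15/15 (or per ``config.split_fractions``); scaling parameters
    are fitted on the training split only.  Stops when validation MSE fails
    to improve for ``val_patience`` consecutive epochs, restoring the
    best-validation weights.  Returns ``(network, record, splits)``.
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise SchemaError("feature/target row counts differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ParameterError("non-finite features or targets")

    if splits is None:
        splits = split_dataset(X.shape[0], config.split_fractions, config.seed)
    idx_train, idx_val, idx_test = splits

    input_scaling = AffineScaling.fit(X[idx_train])
    target_scaling = AffineScaling.fit(y[idx_train][:, None])
    net = init_network(
        config.seed,
        n_inputs=X.shape[1],
        n_hidden=n_hidden,
        input_scaling=input_scaling,
        target_scaling=target_scaling,
    )

    Xs = input_scaling.transform(X)
    ys = target_scaling.transform(y[:, None]).ravel()
    Xtr, ytr = Xs[idx_train], ys[idx_train]
    Xva, yva = Xs[idx_val], ys[idx_val]
    Xte, yte = Xs[idx_test], ys[idx_test]

    record = TrainingRecord()
    best_val = np.inf
    best_weights = None
    fails = 0
    lr = config.learning_rate

    for epoch in range(config.max_epochs):
        # overflow during a diverging run is expected; caught via isfinite
        with np.errstate(over="ignore", invalid="ignore"):
            loss, dW1, db1, dW2, db2 = loss_and_gradients(net, Xtr, ytr)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            record.train_mse.append(loss)
            val = mse(net.forward_scaled(Xva), yva) if len(idx_val) else np.nan
            record.val_mse.append(val)
            record.test_mse.append(
                mse(net.forward_scaled(Xte), yte) if len(idx_test) else np.nan
            )

        monitored = val if len(idx_val) else loss
        if monitored < best_val - 1e-15:
            best_val = monitored
            best_weights = (net.W1.copy(), net.b1.copy(), net.W2.copy(), net.b2)
            record.best_epoch = epoch
            fails = 0
        else:
            fails += 1
            if fails >= config.val_patience:
                record.stop_reason = "early_stopping"
                break

        with np.errstate(over="ignore", invalid="ignore"):
            net.W1 -= lr * dW1
            net.b1 -= lr * db1
            net.W2 -= lr * dW2
            net.b2 -= lr * db2
    else:
        record.stop_reason = "max_epochs"

    if best_weights is not None:
        net.W1, net.b1, net.W2, net.b2 = best_weights
    return net, record, (idx_train, idx_val, idx_test)


def predict(net: BMDNetwork, X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass on a (n, n_features) array of raw features."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ParameterError("non-finite feature value")
    if X.shape[1] != net.n_inputs:
        raise SchemaError(f"expected {net.n_inputs} feature columns, got {X.shape[1]}")
    ys = net.forward_scaled(net.input_scaling.transform(X))
    return net.target_scaling.inverse(ys[:, None]).ravel()


def _feature_row(features, n_inputs: int) -> np.ndarray:
    from .texture import TextureFeatureVector

    if isinstance(features, TextureFeatureVector):
        return features.as_array()
    x = np.asarray(features, dtype=float).ravel()
    if x.size != n_inputs:
        raise SchemaError(f"expected {n_inputs} features, got {x.size}")
    return x
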