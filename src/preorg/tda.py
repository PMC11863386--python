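"""Targeted-discriminant-analysis collective variables.

A small feed-forward network maps the switch-normalized distance features to
a single scalar CV. Training does not use classification targets; instead,
the per-class distributions of the CV output are driven toward prescribed
Gaussian targets (center mu~_c, width sigma~_c) by the loss

    L = sum_c [ (mu_c - mu~_c)^2 + alpha * (sigma_c - sigma~_c)^2 ],

where mu_c and sigma_c are the batch mean and standard deviation of the CV
over class c. With the canonical three-class targets (-10, 0, 10) and widths
(0.4, 0.3, 0.4), the reactant-, intermediate- and product-like states are
pinned to well-separated CV regions, so barriers between them become
crossable by a 1-D bias even though no transition-state configurations ever
enter the training set.

The network, loss, gradients and Adam optimizer are implemented directly in
numpy so trained models are a plain, portable bundle of arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError, BatchError, ConfigError, DimensionError

__all__ = [
    "TDATargets",
    "MLPSpec",
    "TrainConfig",
    "CVModel",
    "tda_loss",
    "tda_loss_and_output_grad",
    "train_cv",
    "evaluate_cv",
]


@dataclass(frozen=True)
class TDATargets:
    """Per-class target centers and widths of the CV output distribution."""

    centers: tuple = (-10.0, 0.0, 10.0)
    sigmas: tuple = (0.4, 0.3, 0.4)
    alpha: float = 1.0

    def __post_init__(self) -> None:
        centers = tuple(float(c) for c in self.centers)
        sigmas = tuple(float(s) for s in self.sigmas)
        if len(centers) != len(sigmas):
            raise ArgumentError("one (center, sigma) pair per class required")
        if np.any(np.diff(centers) <= 0):
            raise ArgumentError("centers must be strictly increasing")
        if any(s <= 0 for s in sigmas):
            raise ArgumentError("sigmas must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "sigmas", sigmas)

    @property
    def n_classes(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class MLPSpec:
    """Network architecture: e.g. (36, 72, 36, 1) or (28, 56, 28, 1)."""

    layer_widths: tuple
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        widths = tuple(int(w) for w in self.layer_widths)
        if len(widths) < 2:
            raise ConfigError("at least an input and an output layer required")
        if widths[-1] != 1:
            raise ConfigError("the CV output layer must have width 1")
        if any(w < 1 for w in widths):
            raise ConfigError("layer widths must be positive")
        if self.activation not in ("tanh", "relu"):
            raise ConfigError(f"unsupported activation {self.activation!r}")
        object.__setattr__(self, "layer_widths", widths)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, full-batch, 80/20 split by default)."""

    learning_rate: float = 1e-2
    max_epochs: int = 2000
    val_fraction: float = 0.2
    loss_threshold: float = 0.02
    patience: int = 200
    min_rel_improvement: float = 1e-4


def _group_by_class(values: np.ndarray, labels: np.ndarray, n_classes: int) -> list:
    groups = []
    for c in range(n_classes):
        g = values[labels == c]
        if g.size < 2:
            raise BatchError(f"class {c} has fewer than 2 samples in the batch")
        groups.append(g)
    return groups


def tda_loss(cv_by_class, targets: TDATargets) -> float:
    """Distribution-matching loss over per-class CV batches.

    ``cv_by_class`` maps class index -> 1-D array of CV values (or is a
    sequence ordered by class). Zero iff every class batch matches its
    target mean and standard deviation exactly; invariant under within-class
    permutation. Standard deviations are population (ddof = 0) statistics.
    """
    if isinstance(cv_by_class, Mapping):
        groups = [np.asarray(cv_by_class[c], float).ravel() for c in sorted(cv_by_class)]
    else:
        groups = [np.asarray(g, float).ravel() for g in cv_by_class]
    if len(groups) != targets.n_classes:
        raise ArgumentError(
            f"expected {targets.n_classes} class batches, got {len(groups)}"
        )
    loss = 0.0
    for g, mu_t, sd_t in zip(groups, targets.centers, targets.sigmas):
        if g.size < 2:
            raise BatchError("every class batch needs at least 2 samples")
        mu, sd = g.mean(), g.std()
        loss += (mu - mu_t) ** 2 + targets.alpha * (sd - sd_t) ** 2
    return float(loss)


def tda_loss_and_output_grad(
    values: np.ndarray, labels: np.ndarray, targets: TDATargets
) -> tuple[float, np.ndarray]:
    """Loss plus its gradient with respect to each CV output value."""
    values = np.asarray(values, float).ravel()
    labels = np.asarray(labels)
    grad = np.zeros_like(values)
    loss = 0.0
    for c, (mu_t, sd_t) in enumerate(zip(targets.centers, targets.sigmas)):
        mask = labels == c
        g = values[mask]
        if g.size < 2:
            raise BatchError(f"class {c} has fewer than 2 samples in the batch")
        n = g.size
        mu, sd = g.mean(), g.std()
        loss += (mu - mu_t) ** 2 + targets.alpha * (sd - sd_t) ** 2
        dmu = 2.0 * (mu - mu_t) / n
        if sd > 0:
            dsd = 2.0 * targets.alpha * (sd - sd_t) * (g - mu) / (n * sd)
        else:
            dsd = 0.0
        grad[mask] = dmu + dsd
    return float(loss), grad


class _MLP:
    """Plain numpy multilayer perceptron with manual backprop."""

    def __init__(self, spec: MLPSpec, rng: np.random.Generator):
        self.spec = spec
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        widths = spec.layer_widths
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))  # Xavier-uniform
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def _act(self, a: np.ndarray) -> np.ndarray:
        return np.tanh(a) if self.spec.activation == "tanh" else np.maximum(a, 0.0)

    def _act_grad(self, z: np.ndarray) -> np.ndarray:
        if self.spec.activation == "tanh":
            return 1.0 - z * z
        return (z > 0).astype(float)

    def forward(self, x: np.ndarray, cache: bool = False):
        z = x
        acts = [z]
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = z @ w + b
            z = a if i == n_layers - 1 else self._act(a)
            if cache:
                acts.append(z)
        return (z, acts) if cache else z

    def backward(self, acts: list, dout: np.ndarray):
        """Parameter gradients and the gradient w.r.t. the network input."""
        grads_w, grads_b = [], []
        delta = dout
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * self._act_grad(acts[i])
        dinput = delta @ self.weights[0].T
        return grads_w[::-1], grads_b[::-1], dinput

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: Sequence[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [np.asarray(p, float) for p in params[:n]]
        self.biases = [np.asarray(p, float) for p in params[n:]]


class _Adam:
    def __init__(self, params: list, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list, grads: list) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class CVModel:
    """A trained discriminant CV: weights, normalization, targets, history.

    Inputs are standardized by the training-set mean/sd stored on the model,
    so deployment is self-contained. ``status`` records how training ended:
    "converged" (validation loss under the threshold), "early_stop"
    (patience exhausted, with warning) or "max_epochs".
    """

    net: _MLP
    spec: MLPSpec
    targets: TDATargets
    input_mean: np.ndarray
    input_std: np.ndarray
    history: list
    status: str = "converged"

    def evaluate(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, float))
        if x.shape[1] != self.spec.layer_widths[0]:
            raise DimensionError(
                f"feature dimension {x.shape[1]} != network input {self.spec.layer_widths[0]}"
            )
        z = (x - self.input_mean) / self.input_std
        return self.net.forward(z).ravel()

    def input_gradient(self, features: np.ndarray) -> np.ndarray:
        """d(CV)/d(features) per sample, through the standardization."""
        x = np.atleast_2d(np.asarray(features, float))
        z = (x - self.input_mean) / self.input_std
        _, acts = self.net.forward(z, cache=True)
        dout = np.ones((z.shape[0], 1))
        _, _, dz = self.net.backward(acts, dout)
        return dz / self.input_std

    @property
    def final_validation_loss(self) -> float:
        return self.history[-1]["val_loss"]

    # -- portable single-file serialization (JSON) ------------------------
    def save(self, path) -> None:
        doc = {
            "spec": {
                "layer_widths": list(self.spec.layer_widths),
                "activation": self.spec.activation,
                "seed": self.spec.seed,
            },
            "targets": {
                "centers": list(self.targets.centers),
                "sigmas": list(self.targets.sigmas),
                "alpha": self.targets.alpha,
            },
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
            "weights": [w.tolist() for w in self.net.weights],
            "biases": [b.tolist() for b in self.net.biases],
            "history": self.history,
            "status": self.status,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "CVModel":
        with open(path) as fh:
            doc = json.load(fh)
        spec = MLPSpec(tuple(doc["spec"]["layer_widths"]), doc["spec"]["activation"], doc["spec"]["seed"])
        targets = TDATargets(tuple(doc["targets"]["centers"]), tuple(doc["targets"]["sigmas"]), doc["targets"]["alpha"])
        net = _MLP(spec, np.random.default_rng(0))
        net.weights = [np.asarray(w, float) for w in doc["weights"]]
        net.biases = [np.asarray(b, float) for b in doc["biases"]]
        return cls(
            net=net,
            spec=spec,
            targets=targets,
            input_mean=np.asarray(doc["input_mean"], float),
            input_std=np.asarray(doc["input_std"], float),
            history=doc["history"],
            status=doc["status"],
        )


def train_cv(
    features: np.ndarray,
    labels: np.ndarray,
    spec: MLPSpec,
    targets: TDATargets = TDATargets(),
    config: TrainConfig = TrainConfig(),
) -> CVModel:
    """Train the discriminant CV by full-batch Adam on the TDA loss.

    Features are standardized by the training split's mean/sd (constants
    stored on the returned model). The data are shuffled once with the
    spec's seed and split 1 - val_fraction / val_fraction; training stops as
    soon as the validation loss drops below ``config.loss_threshold``
    ("converged"), or after ``patience`` epochs without relative improvement
    ("early_stop", with a warning), or at ``max_epochs``. Training is fully
    deterministic for a fixed seed.
    """
    x = np.asarray(features, float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise DimensionError("features must be 2-D with one label per row")
    classes = np.unique(y)
    if not np.array_equal(classes, np.arange(targets.n_classes)):
        raise ConfigError(
            f"class labels must be exactly 0..{targets.n_classes - 1}, got {classes.tolist()}"
        )
    if x.shape[1] != spec.layer_widths[0]:
        raise ConfigError(
            f"feature dimension {x.shape[1]} does not match first layer width "
            f"{spec.layer_widths[0]}"
        )

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(x.shape[0])
    n_val = max(int(round(config.val_fraction * x.shape[0])), 2 * targets.n_classes)
    val_idx, train_idx = order[:n_val], order[n_val:]
    x_train, y_train = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    mean = x_train.mean(axis=0)
    std = x_train.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    zt = (x_train - mean) / std
    zv = (x_val - mean) / std

    net = _MLP(spec, rng)
    params = net.parameters()
    opt = _Adam(params, config.learning_rate)
    history: list[dict] = []
    best = np.inf
    since_best = 0
    status = "max_epochs"
    for epoch in range(config.max_epochs):
        out, acts = net.forward(zt, cache=True)
        train_loss, dout = tda_loss_and_output_grad(out.ravel(), y_train, targets)
        gw, gb, _ = net.backward(acts, dout[:, None])
        opt.step(params, gw + gb)
        val_out = net.forward(zv).ravel()
        val_loss, _ = tda_loss_and_output_grad(val_out, y_val, targets)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < config.loss_threshold:
            status = "converged"
            break
        if val_loss < best * (1 - config.min_rel_improvement):
            best = val_loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                warnings.warn(
                    f"validation loss stopped improving after {epoch + 1} epochs "
                    f"(best {best:.4g}); early stop",
                    RuntimeWarning,
                )
                status = "early_stop"
                break
    return CVModel(
        net=net,
        spec=spec,
        targets=targets,
        input_mean=mean,
        input_std=std,
        history=history,
        status=status,
    )


def evaluate_cv(model: CVModel, features: np.ndarray, labels=None):
    """CV values for a feature table, plus per-class summaries when labeled.

    Returns (values, summary) where summary is a DataFrame with per-class
    mean and standard deviation (ddof = 0) of the CV, or None when no labels
    are given. Evaluation is pure: repeated calls give identical results.
    """
    import pandas as pd

    values = model.evaluate(features)
    if labels is None:
        return values, None
    labels = np.asarray(labels)
    rows = []
    for c in np.unique(labels):
        g = values[labels == c]
        rows.append({"class_index": int(c), "n": g.size, "mean": g.mean(), "sd": g.std()})
    return values, pd.DataFrame(rows)
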