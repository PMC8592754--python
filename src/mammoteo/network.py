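"""A small 1-D convolutional classifier trained by neuroevolution.

The network consumes the texture feature vector as a 1-D signal:

    conv(filters, kernel, stride) -> ReLU -> max-pool -> dense -> ReLU
    -> dense(M classes) -> softmax

All parameters live in one flat weight vector so the whole network can
be handed to the thermal-exchange optimizer as a box-bounded search
problem; the training objective is the mean squared error between the
softmax outputs and one-hot targets (no gradients anywhere).
Cross-entropy (optionally L2-penalized) is available as a diagnostic.

Evaluation metrics are the standard confusion-matrix ratios in percent:
accuracy (TP+TN)/(TP+TN+FP+FN), sensitivity TP/(TP+FN) and specificity
TN/(TN+FP), with the malignant class as positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .optimize import Candidate, TEOConfig, run_ateo

__all__ = [
    "NetworkSpec",
    "ConfusionCounts",
    "UndefinedMetricError",
    "forward",
    "predict",
    "softmax",
    "cross_entropy",
    "mse_fitness",
    "train_with_ateo",
    "confusion_counts",
    "evaluate_metrics",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the 1-D convolutional classifier."""

    input_len: int = 10
    conv_filters: int = 4
    kernel: int = 3
    stride: int = 1
    pool: int = 2
    hidden: int = 8
    classes: int = 2

    @property
    def conv_out(self) -> int:
        return (self.input_len - self.kernel) // self.stride + 1

    @property
    def pooled(self) -> int:
        return self.conv_out // self.pool

    @property
    def flat(self) -> int:
        return self.pooled * self.conv_filters

    def shapes(self) -> List[Tuple[str, Tuple[int, ...]]]:
        return [
            ("conv_w", (self.conv_filters, self.kernel)),
            ("conv_b", (self.conv_filters,)),
            ("dense1_w", (self.flat, self.hidden)),
            ("dense1_b", (self.hidden,)),
            ("dense2_w", (self.hidden, self.classes)),
            ("dense2_b", (self.classes,)),
        ]

    @property
    def weight_count(self) -> int:
        return sum(int(np.prod(s)) for _, s in self.shapes())

    def unflatten(self, w: np.ndarray) -> Dict[str, np.ndarray]:
        w = np.asarray(w, dtype=float)
        if w.shape != (self.weight_count,):
            raise ValueError(f"expected {self.weight_count} weights, got {w.shape}")
        out, k = {}, 0
        for name, shape in self.shapes():
            size = int(np.prod(shape))
            out[name] = w[k : k + size].reshape(shape)
            k += size
        return out

    def flatten(self, params: Dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([np.asarray(params[name]).ravel() for name, _ in self.shapes()])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(spec: NetworkSpec, weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Class probabilities for one feature vector or a batch (n, input_len)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != spec.input_len:
        raise ValueError(f"expected input length {spec.input_len}, got {X.shape[1]}")
    p = spec.unflatten(weights)

    windows = np.lib.stride_tricks.sliding_window_view(X, spec.kernel, axis=1)
    windows = windows[:, :: spec.stride, :]  # (n, conv_out, kernel)
    conv = np.einsum("nok,fk->nof", windows, p["conv_w"]) + p["conv_b"]
    conv = np.maximum(conv, 0.0)

    usable = spec.pooled * spec.pool
    pooled = conv[:, :usable, :].reshape(X.shape[0], spec.pooled, spec.pool, spec.conv_filters)
    pooled = pooled.max(axis=2)

    flat = pooled.reshape(X.shape[0], spec.flat)
    h = np.maximum(flat @ p["dense1_w"] + p["dense1_b"], 0.0)
    logits = h @ p["dense2_w"] + p["dense2_b"]
    probs = softmax(logits)
    return probs if np.asarray(x).ndim > 1 else probs[0]


def predict(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Class decisions: argmax probability, ties toward the benign class
    (lowest index)."""
    probs = np.atleast_2d(forward(spec, weights, X))
    return probs.argmax(axis=1)


def cross_entropy(
    probabilities: np.ndarray,
    targets: np.ndarray,
    weights: Optional[np.ndarray] = None,
    rho: float = 0.0,
) -> float:
    """Summed cross-entropy of one-hot targets, plus an optional L2
    weight penalty (rho/2) * sum(w^2).  Natural-log convention.

    Zero probabilities at a target class are clipped at 1e-12.
    """
    Z = np.atleast_2d(np.asarray(probabilities, dtype=float))
    D = np.atleast_2d(np.asarray(targets, dtype=float))
    if Z.shape != D.shape:
        raise ValueError("probabilities and targets must share a shape")
    loss = float(-np.sum(D * np.log(np.clip(Z, 1e-12, None))))
    if rho and weights is not None:
        loss += 0.5 * rho * float(np.sum(np.asarray(weights) ** 2))
    return loss


def mse_fitness(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean squared error between softmax outputs and one-hot targets,
    normalized by the number of samples — the neuroevolution objective."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    probs = np.atleast_2d(forward(spec, weights, X))
    if probs.shape != Y.shape:
        raise ValueError("targets must be one-hot with shape (n, classes)")
    return float(np.sum((probs - Y) ** 2) / Y.shape[0])


def fit_scaler(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and standard deviation for z-score scaling.

    GLCM statistics span several orders of magnitude (contrast in the
    thousands, homogeneity below 1); standardizing on the training set
    keeps the box-bounded weight search well conditioned.  Constant
    features get unit scale.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def apply_scaler(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - mu) / sd


def one_hot(labels: np.ndarray, classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def train_with_ateo(
    spec: NetworkSpec,
    X: np.ndarray,
    Y: np.ndarray,
    config: Optional[TEOConfig] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, "pd.DataFrame"]:
    """Search the flat weight vector with ATEO minimizing the MSE.

    Default search box is [-5, 5] per weight with a population of 150;
    returns (best weights, optimizer history).  The best-so-far training
    MSE in the history is non-increasing by elitism.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 0:
        raise ValueError("empty dataset")
    w = spec.weight_count
    if config is None:
        cfg = TEOConfig(lower=-5.0, upper=5.0, pop_size=150, max_fes=20_000, seed=seed)
    else:
        cfg = replace(config, seed=seed)

    def objective(vec: np.ndarray) -> float:
        return mse_fitness(spec, vec, X, Y)

    best, history = run_ateo(objective, w, cfg)
    return best.position, history


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is empty (e.g. no positive samples)."""


def confusion_counts(predicted: np.ndarray, actual: np.ndarray, positive: int = 1) -> ConfusionCounts:
    p = np.asarray(predicted) == positive
    a = np.asarray(actual) == positive
    return ConfusionCounts(
        tp=int(np.sum(p & a)),
        tn=int(np.sum(~p & ~a)),
        fp=int(np.sum(p & ~a)),
        fn=int(np.sum(~p & a)),
    )


def evaluate_metrics(counts: ConfusionCounts) -> Tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %) from confusion counts."""
    if counts.total == 0:
        raise UndefinedMetricError("no samples evaluated")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    accuracy = 100.0 * (counts.tp + counts.tn) / counts.total
    sensitivity = 100.0 * counts.tp / (counts.tp + counts.fn)
    specificity = 100.0 * counts.tn / (counts.tn + counts.fp)
    return accuracy, sensitivity, specificity
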