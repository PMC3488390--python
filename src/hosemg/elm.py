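"""Extreme learning machine: random hidden layer, analytic output weights.

A single-hidden-layer feed-forward network in which the input weights W and
hidden biases b are drawn randomly (uniform on [-1, 1]) and *never*
trained; only the hidden-to-output weights are fitted, by minimum-norm
least squares:

    H[i, j] = g(W[j] . x_i + b[j]),      beta = pinv(H) @ Y,

where g is the activation (logistic sigmoid by default), Y is the one-hot
target matrix and pinv the Moore-Penrose pseudoinverse, so beta minimizes
||H beta - Y|| and has minimal norm among minimizers.  Features are affinely
scaled to [-1, 1] using training extremes before entering the network (the
QPC feature D spans orders of magnitude).  Prediction takes the argmax
output node; ties resolve to the first class in the (alphabetical) class
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureTable",
    "ELMModel",
    "elm_train",
    "elm_predict",
    "accuracy",
    "save_model",
    "load_model",
    "ACTIVATIONS",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


ACTIVATIONS = {
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
    "hardlim": lambda z: (z >= 0).astype(float),
}


@dataclass
class FeatureTable:
    """Samples x features matrix with parallel class labels."""

    features: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] == 1 and len(self.labels) != 1:
            self.features = self.features.T
        if self.features.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.features.shape[0]} feature rows vs {len(self.labels)} labels"
            )
        if len(self.labels) == 0:
            raise ValueError("feature table is empty")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature table contains non-finite values")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def one_hot(self, classes: list[str] | None = None) -> np.ndarray:
        classes = classes if classes is not None else self.classes
        index = {c: k for k, c in enumerate(classes)}
        Y = np.zeros((len(self.labels), len(classes)))
        for i, lab in enumerate(self.labels):
            Y[i, index[lab]] = 1.0
        return Y

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ELMModel:
    input_weights: np.ndarray  # (n_hidden, n_features)
    biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden, n_classes)
    activation: str
    classes: list[str]
    scale_min: np.ndarray  # per-feature training minima
    scale_max: np.ndarray  # per-feature training maxima
    seed: int = 0

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


def _scale(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Affine map sending training [lo, hi] to [-1, 1] per feature."""
    return 2.0 * (X - lo) / (hi - lo) - 1.0


def _hidden(model_or_parts, X: np.ndarray) -> np.ndarray:
    W, b, act = model_or_parts
    return ACTIVATIONS[act](X @ W.T + b)


def solve_output_weights(
    H: np.ndarray, Y: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Minimum-norm least-squares output weights beta = pinv(H) Y.

    With ``ridge`` > 0 solves the regularized normal equations
    (H'H + ridge I) beta = H'Y instead.
    """
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if ridge > 0.0:
        A = H.T @ H + ridge * np.eye(H.shape[1])
        return np.linalg.solve(A, H.T @ Y)
    return np.linalg.pinv(H) @ Y


def elm_train(
    table: FeatureTable,
    n_hidden: int = 40,
    activation: str = "sigmoid",
    seed: int = 0,
    ridge: float = 0.0,
) -> ELMModel:
    """Fit an ELM: draw W, b from ``seed``, solve beta = pinv(H) Y.

    ``ridge`` > 0 switches to the regularized solve
    (H'H + ridge I)^{-1} H'Y for numerically singular hidden matrices
    (default 0: exact minimum-norm least squares).
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if activation not in ACTIVATIONS:
        raise ValueError(f"activation must be one of {sorted(ACTIVATIONS)}")
    if len(table) < 2:
        raise ValueError("need at least 2 training samples")
    classes = table.classes
    if len(classes) < 2:
        raise ValueError(
            f"training set contains a single class {classes}; need >= 2"
        )
    X = table.features
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    constant = np.isclose(hi, lo)
    if np.any(constant):
        bad = np.flatnonzero(constant).tolist()
        raise ValueError(f"degenerate constant feature(s) at column(s) {bad}")
    Xs = _scale(X, lo, hi)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = _hidden((W, b, activation), Xs)
    Y = table.one_hot(classes)
    beta = solve_output_weights(H, Y, ridge=ridge)
    return ELMModel(
        input_weights=W,
        biases=b,
        output_weights=beta,
        activation=activation,
        classes=classes,
        scale_min=lo,
        scale_max=hi,
        seed=seed,
    )


def elm_predict(model: ELMModel, features: np.ndarray) -> list[str]:
    """Predict class labels: scale, propagate, argmax over output nodes."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    Xs = _scale(X, model.scale_min, model.scale_max)
    H = _hidden((model.input_weights, model.biases, model.activation), Xs)
    scores = H @ model.output_weights
    # np.argmax returns the first maximum, which realizes the tie rule
    # (first class in the declared alphabetical order).
    return [model.classes[k] for k in np.argmax(scores, axis=1)]


def decision_scores(model: ELMModel, features: np.ndarray) -> np.ndarray:
    """Raw output-node activations H @ beta (one column per class)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    Xs = _scale(X, model.scale_min, model.scale_max)
    H = _hidden((model.input_weights, model.biases, model.activation), Xs)
    return H @ model.output_weights


def accuracy(predicted: list[str], truth: list[str]) -> float:
    """Exact-match fraction of two parallel label vectors."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if len(truth) == 0:
        raise ValueError("empty label vectors")
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def save_model(model: ELMModel, path: str) -> str:
    """Serialize the model to a single self-describing JSON file."""
    payload = {
        "format": "hosemg-elm-1",
        "activation": model.activation,
        "classes": model.classes,
        "seed": model.seed,
        "input_weights": model.input_weights.tolist(),
        "biases": model.biases.tolist(),
        "output_weights": model.output_weights.tolist(),
        "scale_min": np.asarray(model.scale_min).tolist(),
        "scale_max": np.asarray(model.scale_max).tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
    return path


def load_model(path: str) -> ELMModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "hosemg-elm-1":
        raise ValueError(f"{path}: not a hosemg ELM model file")
    return ELMModel(
        input_weights=np.asarray(payload["input_weights"], dtype=float),
        biases=np.asarray(payload["biases"], dtype=float),
        output_weights=np.asarray(payload["output_weights"], dtype=float),
        activation=payload["activation"],
        classes=list(payload["classes"]),
        scale_min=np.asarray(payload["scale_min"], dtype=float),
        scale_max=np.asarray(payload["scale_max"], dtype=float),
        seed=int(payload["seed"]),
    )
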