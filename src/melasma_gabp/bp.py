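"""From-scratch three-layer backpropagation (BP) perceptron.

A single hidden layer of unipolar sigmoid units maps m normalized inputs to
l sigmoid outputs. Both layers carry a bias implemented as a fixed unit
input (x_0 = y_0 = 1), so the input-to-hidden matrix V has shape
(m+1, H) and the hidden-to-output matrix W has shape (H+1, l).

The global error driving training is the mean over samples of the
per-sample squared error  E_s = 1/2 * sum_k (b_k - O_k)^2 ; weights are
updated by plain full-batch gradient descent,  dw = -mu * dE/dw, with no
momentum or regularization. An online (per-sample) update mode is
available for completeness.

Hidden-layer width follows the printed sizing rule H = m + n + a with a in
1..10 (a sqrt(m+n)+a variant is offered), and inputs are min-max scaled to
[0, 1] before training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd


class TrainingDivergedError(RuntimeError):
    """Raised when the global error becomes non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"global error became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters of the perceptron.

    ``n_hidden`` defaults to the sizing rule ``hidden_size(n_input, n_output,
    hidden_size_constant)``. The learning rate and error goal default to the
    values used throughout the evaluation protocol (0.2 and 0.001).
    """

    n_input: int = 5
    n_output: int = 1
    n_hidden: Optional[int] = None
    learning_rate: float = 0.2
    max_epochs: int = 1000
    error_goal: float = 0.001
    hidden_size_constant: int = 4
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_input < 1 or self.n_output < 1:
            raise ValueError("n_input and n_output must be >= 1")
        if not (0.0 < self.learning_rate < 1.0):
            raise ValueError(f"learning_rate must be in (0,1), got {self.learning_rate}")
        if not (1 <= self.hidden_size_constant <= 10):
            raise ValueError("hidden_size_constant must be in [1, 10]")
        if self.error_goal <= 0:
            raise ValueError("error_goal must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be > 0")

    @property
    def hidden(self) -> int:
        """Resolved hidden-layer width."""
        if self.n_hidden is not None:
            if self.n_hidden < 1:
                raise ValueError("n_hidden must be >= 1")
            return self.n_hidden
        return hidden_size(self.n_input, self.n_output, self.hidden_size_constant)


def hidden_size(
    m: int, n: int, a: int, rule: Literal["linear", "sqrt"] = "linear"
) -> int:
    """Hidden-layer width from input count m, output count n and constant a.

    The default rule is H = m + n + a; ``rule="sqrt"`` uses the conventional
    round(sqrt(m + n)) + a form instead. a must lie in 1..10.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if not (1 <= a <= 10):
        raise ValueError(f"constant a must be in [1, 10], got {a}")
    if rule == "linear":
        return m + n + a
    if rule == "sqrt":
        return int(round(math.sqrt(m + n))) + a
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class NetworkWeights:
    """Weight matrices V (input->hidden, (m+1, H)) and W (hidden->output, (H+1, l)).

    Row 0 of each matrix is the bias row, fed by the constant unit input.
    """

    V: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.V.ndim != 2 or self.W.ndim != 2:
            raise ValueError("V and W must be 2-D arrays")
        if self.V.shape[1] + 1 != self.W.shape[0]:
            raise ValueError(
                f"inconsistent shapes: V {self.V.shape} feeds {self.V.shape[1]} hidden "
                f"units but W {self.W.shape} expects {self.W.shape[0] - 1}"
            )
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(self.W))):
            raise ValueError("weights must be finite")

    @property
    def n_input(self) -> int:
        return self.V.shape[0] - 1

    @property
    def n_hidden(self) -> int:
        return self.V.shape[1]

    @property
    def n_output(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.V.copy(), self.W.copy())

    @classmethod
    def random(cls, config: NetworkConfig, rng: np.random.Generator) -> "NetworkWeights":
        """Uniform initialization in [-init_scale, init_scale]."""
        s = config.init_scale
        V = rng.uniform(-s, s, size=(config.n_input + 1, config.hidden))
        W = rng.uniform(-s, s, size=(config.hidden + 1, config.n_output))
        return cls(V, W)


def sigmoid(x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Unipolar sigmoid 1 / (1 + exp(-x)), branch-stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if out.ndim == 0 else out


def _with_bias(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def forward(
    weights: NetworkWeights, x: Union[Sequence[float], np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass; returns (hidden activations, outputs).

    Accepts a single input vector of length m (returns 1-D activations) or a
    batch of shape (n, m) (returns 2-D activations, one row per sample).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != weights.n_input:
        raise ValueError(f"input has {X.shape[1]} features, network expects {weights.n_input}")
    Y = sigmoid(_with_bias(X) @ weights.V)
    O = sigmoid(_with_bias(Y) @ weights.W)
    if single:
        return Y[0], O[0]
    return Y, O


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, B) arrays or a sequence of (x, b) pairs."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, B = dataset
    else:
        pairs = list(dataset)
        if not pairs:
            raise ValueError("dataset must be non-empty")
        X = np.asarray([p[0] for p in pairs], dtype=float)
        B = np.asarray([p[1] for p in pairs], dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    if X.shape[0] == 0:
        raise ValueError("dataset must be non-empty")
    if X.shape[0] != B.shape[0]:
        raise ValueError("feature and target sample counts differ")
    return X, B


def global_error(weights: NetworkWeights, dataset) -> float:
    """Mean over samples of the per-sample squared error 1/2 * sum_k (b_k - O_k)^2."""
    X, B = _as_xy(dataset)
    _, O = forward(weights, X)
    return float(np.mean(0.5 * np.sum((B - O) ** 2, axis=1)))


def _gradients(
    weights: NetworkWeights, X: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic dE/dV, dE/dW for the mean squared-error E over the batch."""
    A = _with_bias(X)
    Y = sigmoid(A @ weights.V)
    Yb = _with_bias(Y)
    O = sigmoid(Yb @ weights.W)
    n = X.shape[0]
    delta_out = -(B - O) * O * (1.0 - O) / n          # (n, l)
    dW = Yb.T @ delta_out                              # (H+1, l)
    delta_hid = (delta_out @ weights.W[1:].T) * Y * (1.0 - Y)  # (n, H)
    dV = A.T @ delta_hid                               # (m+1, H)
    return dV, dW


def backprop_step(
    weights: NetworkWeights,
    dataset,
    learning_rate: float,
    mode: Literal["batch", "online"] = "batch",
) -> NetworkWeights:
    """One gradient-descent update dw = -mu * dE/dw; returns new weights.

    ``mode="batch"`` (default) takes one step on the batch-mean error;
    ``mode="online"`` sweeps the samples in order, one step each.
    """
    if not (0.0 < learning_rate < 1.0):
        raise ValueError(f"learning_rate must be in (0,1), got {learning_rate}")
    X, B = _as_xy(dataset)
    V, W = weights.V.copy(), weights.W.copy()
    if mode == "batch":
        dV, dW = _gradients(NetworkWeights(V, W), X, B)
        V -= learning_rate * dV
        W -= learning_rate * dW
    elif mode == "online":
        for i in range(X.shape[0]):
            dV, dW = _gradients(NetworkWeights(V, W), X[i : i + 1], B[i : i + 1])
            V -= learning_rate * dV
            W -= learning_rate * dW
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NetworkWeights(V, W)


@dataclass
class TrainResult:
    """Outcome of a training run."""

    final_weights: NetworkWeights
    error_history: list[float]
    epochs_run: int
    converged: bool
    ga_initialized: bool = False

    def __post_init__(self) -> None:
        if len(self.error_history) != self.epochs_run:
            raise ValueError("error_history length must equal epochs_run")


def train(
    config: NetworkConfig,
    dataset,
    initial_weights: Optional[NetworkWeights] = None,
    mode: Literal["batch", "online"] = "batch",
) -> TrainResult:
    """Run gradient descent until the error goal is met or max_epochs elapse.

    Inputs are expected already normalized to [0, 1] and targets in [0, 1].
    Initial weights default to a seeded uniform draw in
    [-init_scale, init_scale]; passing ``initial_weights`` (e.g. a
    GA-optimized genome) makes the run start there instead. Deterministic
    given config, data and initial weights.
    """
    X, B = _as_xy(dataset)
    if X.shape[1] != config.n_input or B.shape[1] != config.n_output:
        raise ValueError(
            f"dataset shape ({X.shape[1]} features, {B.shape[1]} targets) does not "
            f"match config ({config.n_input}, {config.n_output})"
        )
    if initial_weights is None:
        rng = np.random.default_rng(config.seed)
        weights = NetworkWeights.random(config, rng)
    else:
        weights = initial_weights.copy()
    history: list[float] = []
    converged = False
    for epoch in range(config.max_epochs):
        try:
            weights = backprop_step(weights, (X, B), config.learning_rate, mode=mode)
        except ValueError as exc:
            if "finite" in str(exc):  # non-finite update, e.g. NaN data
                raise TrainingDivergedError(epoch) from exc
            raise
        err = global_error(weights, (X, B))
        if not math.isfinite(err):
            raise TrainingDivergedError(epoch)
        history.append(err)
        if err <= config.error_goal:
            converged = True
            break
    return TrainResult(
        final_weights=weights,
        error_history=history,
        epochs_run=len(history),
        converged=converged,
    )


@dataclass
class Normalizer:
    """Per-feature min-max scaler X = (I - I_min) / (I_max - I_min).

    Fitted on the training features; constant (degenerate) features map to
    0.5. ``fit`` must be called (or bounds passed) before use.
    """

    minimum: Optional[np.ndarray] = None
    maximum: Optional[np.ndarray] = None

    @property
    def fitted(self) -> bool:
        return self.minimum is not None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("fit requires at least 2 samples")
        self.minimum = X.min(axis=0)
        self.maximum = X.max(axis=0)
        return self

    def _check(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.fitted:
            raise RuntimeError("normalizer used before fit")
        return self.minimum, self.maximum  # type: ignore[return-value]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant features (max == min)."""
        lo, hi = self._check()
        return hi == lo

    def transform(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self._check()
        X = np.asarray(X, dtype=float)
        span = np.where(hi > lo, hi - lo, 1.0)
        scaled = (X - lo) / span
        return np.where(hi > lo, scaled, 0.5)

    def inverse_transform(self, X_scaled: np.ndarray) -> np.ndarray:
        lo, hi = self._check()
        X_scaled = np.asarray(X_scaled, dtype=float)
        return np.where(hi > lo, lo + X_scaled * (hi - lo), lo)


def fit_normalizer(X: np.ndarray) -> Normalizer:
    """Fit a min-max normalizer on training features (>= 2 samples)."""
    return Normalizer().fit(X)


def apply_normalizer(normalizer: Normalizer, X: np.ndarray) -> np.ndarray:
    return normalizer.transform(X)


def invert_normalizer(normalizer: Normalizer, X_scaled: np.ndarray) -> np.ndarray:
    return normalizer.inverse_transform(X_scaled)


@dataclass
class EvaluationReport:
    """Per-sample expected/output/error rows plus their mean absolute error."""

    rows: pd.DataFrame  # columns: sample, expected, output, abs_error
    mean_abs_error: float

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def evaluate(
    weights: NetworkWeights,
    normalizer: Optional[Normalizer],
    dataset,
    sample_ids: Optional[Sequence] = None,
) -> EvaluationReport:
    """Score a test set: one row per sample with absolute error |b - O|.

    ``normalizer`` (if given) is applied to the raw test features; pass
    ``None`` when the features are already scaled. Only single-output
    networks are reported (scalar expected/output per row).
    """
    X, B = _as_xy(dataset)
    if normalizer is not None:
        X = normalizer.transform(X)
    _, O = forward(weights, X)
    if B.shape[1] != 1:
        raise ValueError("evaluation report expects a single-output network")
    ids = list(sample_ids) if sample_ids is not None else list(range(1, X.shape[0] + 1))
    if len(ids) != X.shape[0]:
        raise ValueError("sample_ids length must match the test set")
    abs_err = np.abs(B[:, 0] - O[:, 0])
    rows = pd.DataFrame(
        {"sample": ids, "expected": B[:, 0], "output": O[:, 0], "abs_error": abs_err}
    )
    return EvaluationReport(rows=rows, mean_abs_error=float(abs_err.mean()))


def save_model(path: Union[str, Path], weights: NetworkWeights,
               normalizer: Optional[Normalizer] = None) -> None:
    """Serialize weights (and optional normalizer bounds) as JSON."""
    payload: dict = {
        "V": weights.V.tolist(),
        "W": weights.W.tolist(),
    }
    if normalizer is not None and normalizer.fitted:
        payload["normalizer"] = {
            "minimum": normalizer.minimum.tolist(),  # type: ignore[union-attr]
            "maximum": normalizer.maximum.tolist(),  # type: ignore[union-attr]
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: Union[str, Path]) -> tuple[NetworkWeights, Optional[Normalizer]]:
    payload = json.loads(Path(path).read_text())
    weights = NetworkWeights(np.array(payload["V"]), np.array(payload["W"]))
    normalizer = None
    if "normalizer" in payload:
        normalizer = Normalizer(
            minimum=np.array(payload["normalizer"]["minimum"]),
            maximum=np.array(payload["normalizer"]["maximum"]),
        )
    return weights, normalizer
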