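"""A from-scratch one-hidden-layer perceptron trained by backpropagation.

The network is the classical fully connected multilayer perceptron with one
hidden layer:

.. math::

    y_j = f\\Big(\\sum_i w_{ji} x_i - \\theta_j\\Big), \\qquad
    o_k = f\\Big(\\sum_j w'_{kj} y_j - \\theta'_k\\Big)

trained by full-batch gradient descent on the summed squared-error objective

.. math::

    E = \\tfrac12 \\sum_p \\sum_k (d_k^p - o_k^p)^2

with the standard backpropagated deltas
``delta'_k = (d_k - o_k) f'(v'_k)`` and
``delta_j = (sum_k delta'_k w'_kj) f'(v_j)``.  Biases are trained exactly like
weights on a constant ``-1`` input (hence the subtracted theta above).  The
per-epoch weight step is the summed per-pattern update scaled by the pattern
count; without that scaling the effective step grows linearly with the
training-set size and full-batch descent at useful learning rates diverges
(see docs/methods.md).

``E`` is tracked on the *sum* scale (no division by the number of patterns),
and ``max_error`` — the convergence stop — is defined on that same scale.

The estimator (:class:`BackpropMLP`) follows scikit-learn conventions:
hyperparameters in ``__init__``, ``fit``/``predict``, fitted attributes with
a trailing underscore, so it composes with sklearn model selection.  The
only supported transfer functions are the logistic sigmoid (default) and a
hyperbolic-tangent variant whose output layer is affinely rescaled to
``(0, 1)`` so that one-hot targets remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "sigmoid",
    "size_hidden",
    "NetworkConfig",
    "TrainingSet",
    "TrainingTrace",
    "TrainingDivergedError",
    "BackpropMLP",
    "predict_label",
    "NO_LABEL",
]

#: Sentinel returned when no output clears the confidence threshold.
NO_LABEL = "none"


class TrainingDivergedError(RuntimeError):
    """Weights became non-finite during training."""


def sigmoid(x):
    """Logistic function ``1 / (1 + exp(-x))``, stable over |x| <= ~700."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def size_hidden(n_in: int, n_out: int) -> int:
    """Hidden-layer sizing heuristic ``round(2 * (n_in + n_out) / 3)``.

    Rounding is half away from zero, so 13.33 -> 13 and 13.5 -> 14.  This is
    a starting point, not a law: callers may (and the default posture
    classifiers do) override it with empirically better values.
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("layer sizes must be positive")
    v = ((n_in + n_out) / 3.0) * 2.0
    return int(math.floor(v + 0.5))


# --------------------------------------------------------------------------
# transfer functions: f for the hidden layer, g for the output layer,
# with derivatives expressed in terms of the activations themselves.
# --------------------------------------------------------------------------


class _SigmoidTransfer:
    name = "sigmoid"

    @staticmethod
    def hidden(v):
        return sigmoid(v)

    @staticmethod
    def hidden_deriv(y):
        return y * (1.0 - y)

    out = hidden
    out_deriv = hidden_deriv


class _TanhTransfer:
    """tanh hidden units; output layer is (tanh + 1) / 2 so targets 0/1 are
    asymptotically reachable."""

    name = "tanh"

    @staticmethod
    def hidden(v):
        return np.tanh(v)

    @staticmethod
    def hidden_deriv(y):
        return 1.0 - y * y

    @staticmethod
    def out(v):
        return 0.5 * (np.tanh(v) + 1.0)

    @staticmethod
    def out_deriv(o):
        t = 2.0 * o - 1.0
        return 0.5 * (1.0 - t * t)


_TRANSFERS = {"sigmoid": _SigmoidTransfer, "tanh": _TanhTransfer}


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and training hyperparameters for one network."""

    n_in: int
    n_out: int
    n_hidden: Optional[int] = None  # None -> size_hidden(n_in, n_out)
    learning_rate: float = 0.3
    max_error: float = 0.01  # on the summed-MSE scale
    max_epochs: int = 20000
    transfer: str = "sigmoid"
    seed: int = 0
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.n_in <= 0 or self.n_out <= 0:
            raise ValueError("n_in and n_out must be positive")
        if self.n_hidden is not None and self.n_hidden <= 0:
            raise ValueError("n_hidden must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.max_error < 0:
            raise ValueError("max_error must be >= 0")
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must be positive")
        if self.transfer not in _TRANSFERS:
            raise ValueError(f"unknown transfer: {self.transfer!r}")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be > 0")

    @property
    def hidden(self) -> int:
        return self.n_hidden if self.n_hidden is not None else size_hidden(self.n_in, self.n_out)


@dataclass
class TrainingSet:
    """Labeled feature matrix: rows in [0, 1], string class labels."""

    X: np.ndarray
    y: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one label per row")
        if not self.labels:
            self.labels = tuple(sorted(set(map(str, self.y))))

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class TrainingTrace:
    """Per-epoch summed MSE plus the stop condition that was reached."""

    errors: np.ndarray
    final_epoch: int
    converged: bool


class BackpropMLP(ClassifierMixin, BaseEstimator):
    """One-hidden-layer perceptron classifier trained by batch backprop.

    Parameters
    ----------
    n_hidden:
        Hidden units; ``None`` applies :func:`size_hidden`.
    learning_rate, max_error, max_epochs:
        Gradient step size, summed-MSE stop threshold and epoch cap.
    transfer:
        ``"sigmoid"`` or ``"tanh"`` (tanh output rescaled to (0, 1)).
    init_scale:
        Weights and biases start uniform in ``[-init_scale, init_scale]``.
    random_state:
        Seed for the weight initialization; training is bit-reproducible
        for a fixed seed and configuration.

    Attributes
    ----------
    w_hidden_, b_hidden_, w_out_, b_out_:
        Fitted weights/biases (``x @ w_hidden_ - b_hidden_`` etc.).
    classes_, loss_curve_, n_epochs_, converged_
    """

    def __init__(
        self,
        n_hidden: Optional[int] = None,
        learning_rate: float = 0.3,
        max_error: float = 0.01,
        max_epochs: int = 20000,
        transfer: str = "sigmoid",
        init_scale: float = 0.5,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.max_error = max_error
        self.max_epochs = max_epochs
        self.transfer = transfer
        self.init_scale = init_scale
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate_X(self, X, fitting: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not fitting and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match the "
                f"network's {self.n_features_in_} inputs"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def forward(self, X):
        """Hidden activations and outputs for ``X`` (row per pattern)."""
        X = self._validate_X(X, fitting=False)
        tf = _TRANSFERS[self.transfer]
        Y = tf.hidden(X @ self.w_hidden_ - self.b_hidden_)
        O = tf.out(Y @ self.w_out_ - self.b_out_)
        return Y, O

    def mse(self, X, y) -> float:
        """Summed squared error ``0.5 * sum_p sum_k (d - o)^2`` against the
        one-hot encoding of ``y``."""
        X = self._validate_X(X, fitting=False)
        if len(X) == 0:
            raise ValueError("mse of an empty set is undefined")
        D = self._one_hot(np.asarray(y))
        _, O = self.forward(X)
        return float(0.5 * np.sum((D - O) ** 2))

    def _one_hot(self, y) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes_)}
        try:
            cols = np.array([index[v] for v in y])
        except KeyError as exc:
            raise ValueError(f"unknown label {exc.args[0]!r}") from None
        D = np.zeros((len(y), len(self.classes_)))
        D[np.arange(len(y)), cols] = 1.0
        return D

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = self._validate_X(X, fitting=True)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty training set")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        n_in, n_out = X.shape[1], len(self.classes_)
        n_hidden = self.n_hidden if self.n_hidden is not None else size_hidden(n_in, n_out)
        if n_hidden <= 0:
            raise ValueError("n_hidden must be positive")
        tf = _TRANSFERS[self.transfer]
        D = self._one_hot(y)

        rng = np.random.default_rng(self.random_state)
        s = self.init_scale
        W1 = rng.uniform(-s, s, size=(n_in, n_hidden))
        b1 = rng.uniform(-s, s, size=n_hidden)
        W2 = rng.uniform(-s, s, size=(n_hidden, n_out))
        b2 = rng.uniform(-s, s, size=n_out)

        eps = self.learning_rate / len(X)  # summed update, step scaled by P
        errors = []
        converged = False
        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            Y = tf.hidden(X @ W1 - b1)
            O = tf.out(Y @ W2 - b2)
            E = 0.5 * np.sum((D - O) ** 2)
            if not np.isfinite(E):
                raise TrainingDivergedError(f"non-finite training error at epoch {epoch}")
            errors.append(E)
            if E <= self.max_error:
                converged = True
                break
            Dk = (D - O) * tf.out_deriv(O)  # delta'_k per pattern
            Dj = (Dk @ W2.T) * tf.hidden_deriv(Y)  # delta_j per pattern
            W2 += eps * (Y.T @ Dk)
            b2 += eps * (-Dk.sum(axis=0))  # bias = weight on constant -1 input
            W1 += eps * (X.T @ Dj)
            b1 += eps * (-Dj.sum(axis=0))
        for arr in (W1, b1, W2, b2):
            if not np.all(np.isfinite(arr)):
                raise TrainingDivergedError("non-finite weights after training")

        self.w_hidden_, self.b_hidden_ = W1, b1
        self.w_out_, self.b_out_ = W2, b2
        self.loss_curve_ = np.asarray(errors)
        self.n_epochs_ = epoch
        self.converged_ = converged
        return self

    def training_trace(self) -> TrainingTrace:
        return TrainingTrace(
            errors=self.loss_curve_, final_epoch=self.n_epochs_, converged=self.converged_
        )

    def decision_function(self, X) -> np.ndarray:
        """Raw output activations (one column per class, values in (0, 1))."""
        _, O = self.forward(X)
        return O

    def predict(self, X) -> np.ndarray:
        O = self.decision_function(X)
        return self.classes_[np.argmax(O, axis=1)]


def predict_label(
    outputs,
    labels: Sequence[str],
    confidence_threshold: float = 0.5,
    margin: float = 0.05,
) -> str:
    """Decode one output vector to a class name, or ``"none"``.

    The winning output must reach ``confidence_threshold`` and beat the
    runner-up by at least ``margin``; otherwise no confident label exists.
    Exact ties resolve to the lowest output index before the margin rule
    rejects them.
    """
    outputs = np.asarray(outputs, dtype=float).ravel()
    if len(outputs) != len(labels):
        raise ValueError("outputs and labels length mismatch")
    top = int(np.argmax(outputs))
    if outputs[top] < confidence_threshold:
        return NO_LABEL
    if len(outputs) > 1:
        runner = float(np.partition(outputs, -2)[-2])
        if outputs[top] - runner < margin:
            return NO_LABEL
    return str(labels[top])
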