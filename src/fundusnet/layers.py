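"""Reference implementations of the elementary network layer equations.

These are small, dependency-light functions used throughout the test suite
to cross-check the trainable layers in :mod:`fundusnet.nn`.  Each function
implements the textbook form of the operation:

* batch normalisation with population (1/n) batch variance,
* ReLU, logistic sigmoid (and its derivative), numerically stable softmax,
* a single LSTM cell step with forget/input/output gates.

The two code paths — these references and the trainable layers — are written
independently and compared in tests, which guards both against transcription
errors in the heavier implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BNParams",
    "LSTMParams",
    "LSTMState",
    "batch_normalize",
    "relu",
    "sigmoid",
    "sigmoid_derivative",
    "softmax",
    "lstm_step",
]


@dataclass
class BNParams:
    """Scalar affine parameters of batch normalisation.

    ``alpha`` is the learned scale, ``beta`` the learned shift, and
    ``epsilon`` the variance stabiliser added before the square root.
    """

    alpha: float = 1.0
    beta: float = 0.0
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class LSTMParams:
    """Gate weights of an LSTM cell acting on the concatenation [h, x].

    Each of ``Wf, Wi, Wc, Wo`` has shape ``(units, units + input_dim)``;
    the biases have length ``units``.
    """

    Wf: np.ndarray
    Wi: np.ndarray
    Wc: np.ndarray
    Wo: np.ndarray
    bf: np.ndarray = field(default=None)  # type: ignore[assignment]
    bi: np.ndarray = field(default=None)  # type: ignore[assignment]
    bc: np.ndarray = field(default=None)  # type: ignore[assignment]
    bo: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Wf = np.atleast_2d(np.asarray(self.Wf, dtype=float))
        self.Wi = np.atleast_2d(np.asarray(self.Wi, dtype=float))
        self.Wc = np.atleast_2d(np.asarray(self.Wc, dtype=float))
        self.Wo = np.atleast_2d(np.asarray(self.Wo, dtype=float))
        shape = self.Wf.shape
        for name, W in (("Wi", self.Wi), ("Wc", self.Wc), ("Wo", self.Wo)):
            if W.shape != shape:
                raise ValueError(
                    f"weight matrix {name} has shape {W.shape}, expected {shape}"
                )
        units = shape[0]
        for name in ("bf", "bi", "bc", "bo"):
            b = getattr(self, name)
            b = np.zeros(units) if b is None else np.asarray(b, dtype=float).ravel()
            if b.shape != (units,):
                raise ValueError(f"bias {name} has length {b.size}, expected {units}")
            setattr(self, name, b)

    @property
    def units(self) -> int:
        return self.Wf.shape[0]

    @property
    def input_dim(self) -> int:
        return self.Wf.shape[1] - self.units


@dataclass
class LSTMState:
    """Hidden vector ``h`` and cell state ``C`` of an LSTM cell."""

    h: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.C = np.asarray(self.C, dtype=float).ravel()
        if self.h.shape != self.C.shape:
            raise ValueError("h and C must have the same length")

    @classmethod
    def zeros(cls, units: int) -> "LSTMState":
        return cls(h=np.zeros(units), C=np.zeros(units))


def batch_normalize(batch: np.ndarray, params: BNParams | None = None) -> np.ndarray:
    """Normalise a batch to zero mean / unit variance, then apply the affine map.

    Uses the population (1/n) variance of the batch.  Returns
    ``alpha * (x - mean) / sqrt(var + eps) + beta`` elementwise.
    """
    params = params or BNParams()
    x = np.asarray(batch, dtype=float)
    if x.size == 0:
        raise ValueError("batch_normalize requires a non-empty batch")
    mu = x.mean()
    var = np.mean((x - mu) ** 2)
    x_hat = (x - mu) / np.sqrt(var + params.epsilon)
    return params.alpha * x_hat + params.beta


def relu(x):
    """Rectified linear unit, ``max(0, x)``, elementwise."""
    return np.maximum(0, np.asarray(x, dtype=float))


def sigmoid(z):
    """Logistic function ``1 / (1 + exp(-z))``, elementwise and overflow-safe."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def sigmoid_derivative(z):
    """Derivative of the logistic function, ``sigma(z) * (1 - sigma(z))``."""
    s = sigmoid(z)
    return s * (1.0 - s)


def softmax(a: np.ndarray) -> np.ndarray:
    """Stable softmax of a vector: exponentials normalised to sum to one.

    The maximum is subtracted before exponentiation, which leaves the result
    unchanged (shift invariance) but avoids overflow.
    """
    a = np.asarray(a, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    e = np.exp(a - a.max())
    return e / e.sum()


def lstm_step(x_t: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM cell update.

    Gates are sigmoids of affine maps of ``[h_{t-1}, x_t]``; the candidate
    cell state uses tanh.  The cell state combines the gated previous state
    and the gated candidate; the hidden state is the output gate times
    ``tanh(C_t)``.
    """
    x_t = np.asarray(x_t, dtype=float).ravel()
    if x_t.size != params.input_dim:
        raise ValueError(
            f"input has length {x_t.size}, weight matrices expect {params.input_dim}"
        )
    if state.h.size != params.units:
        raise ValueError(
            f"state has {state.h.size} units, weight matrices expect {params.units}"
        )
    z = np.concatenate([state.h, x_t])
    f = sigmoid(params.Wf @ z + params.bf)
    i = sigmoid(params.Wi @ z + params.bi)
    c_tilde = np.tanh(params.Wc @ z + params.bc)
    C = f * state.C + i * c_tilde
    o = sigmoid(params.Wo @ z + params.bo)
    h = o * np.tanh(C)
    return LSTMState(h=h, C=C)
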