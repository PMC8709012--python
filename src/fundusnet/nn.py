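"""A compact trainable neural-network engine on numpy arrays.

Implements exactly the layer set the residual CNN+LSTM architecture needs —
2-D convolution, batch normalisation, ReLU, residual blocks, an LSTM that
reduces a sequence to its final hidden state, dense layers, dropout, a
softmax cross-entropy head, and SGD with momentum — each with a hand-written
backward pass.  Tensors are laid out NHWC; sequences are (batch, time,
features).

Every layer follows the same contract: ``forward(x, train)`` caches what the
backward pass needs, ``backward(dout)`` returns the gradient with respect to
the input and accumulates parameter gradients in ``Param.grad``.  Gradient
correctness is established against central finite differences in the test
suite, and the inference-mode behaviour of BatchNorm2d and LSTM is checked
against the independent reference functions in :mod:`fundusnet.layers`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """3x3-style convolution with 'same' padding and integer stride, NHWC."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = k * k * in_channels
        self.W = Param(_he_normal(rng, (k, k, in_channels, out_channels), fan_in), f"{name}.W")
        self.b = Param(np.zeros(out_channels), f"{name}.b")
        self.kernel_size = k
        self.stride = stride
        self.pad = k // 2
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_size(self, h: int) -> int:
        return (h + 2 * self.pad - self.kernel_size) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.pad
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (B, H', W', C, k, k) -> (B, Ho, Wo, k, k, C)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        win = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        Ho, Wo = win.shape[1], win.shape[2]
        cols = win.reshape(B, Ho, Wo, k * k * C)
        Wmat = self.W.value.reshape(k * k * C, -1)
        out = cols @ Wmat + self.b.value
        self._cache = (cols, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        k, s, p = self.kernel_size, self.stride, self.pad
        B, H, W, C = x_shape
        Ho, Wo = dout.shape[1], dout.shape[2]
        F = dout.shape[3]
        cols2 = cols.reshape(-1, k * k * C)
        dout2 = dout.reshape(-1, F)
        self.W.grad += (cols2.T @ dout2).reshape(self.W.value.shape)
        self.b.grad += dout2.sum(axis=0)
        dcols = (dout2 @ self.W.value.reshape(k * k * C, F).T).reshape(B, Ho, Wo, k, k, C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C))
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + s * Ho : s, kj : kj + s * Wo : s, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p : p + H, p : p + W, :]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (batch, height, width).

    Training mode uses the population (1/n) batch variance and maintains
    exponential running statistics; inference mode uses the running
    statistics, matching the scalar reference in :func:`fundusnet.layers.batch_normalize`.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mu) * inv_std
        self._cache = (x_hat, inv_std, axes, train)
        return self.gamma.value * x_hat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat, inv_std, axes, train = self._cache
        n = int(np.prod([dout.shape[a] for a in axes]))
        self.gamma.grad += (dout * x_hat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        if not train:
            return dxhat * inv_std
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=axes) - x_hat * (dxhat * x_hat).sum(axis=axes))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "fc",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_normal(rng, (in_features, out_features), in_features), f"{name}.W")
        self.b = Param(np.zeros(out_features), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """LSTM over (batch, time, features) returning the final hidden state.

    Gate weights act on the concatenation [h_{t-1}, x_t], the same layout as
    :class:`fundusnet.layers.LSTMParams`, so the two implementations can be
    compared parameter-for-parameter.
    """

    def __init__(
        self,
        input_dim: int,
        units: int,
        rng: np.random.Generator | None = None,
        name: str = "lstm",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.units = units
        self.input_dim = input_dim
        d = units + input_dim
        scale = 1.0 / np.sqrt(d)
        self.Wf = Param(rng.uniform(-scale, scale, (units, d)), f"{name}.Wf")
        self.Wi = Param(rng.uniform(-scale, scale, (units, d)), f"{name}.Wi")
        self.Wc = Param(rng.uniform(-scale, scale, (units, d)), f"{name}.Wc")
        self.Wo = Param(rng.uniform(-scale, scale, (units, d)), f"{name}.Wo")
        # forget-gate bias starts at 1 so early training does not erase state
        self.bf = Param(np.ones(units), f"{name}.bf")
        self.bi = Param(np.zeros(units), f"{name}.bi")
        self.bc = Param(np.zeros(units), f"{name}.bc")
        self.bo = Param(np.zeros(units), f"{name}.bo")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.Wf, self.Wi, self.Wc, self.Wo, self.bf, self.bi, self.bc, self.bo]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, D = x.shape
        if D != self.input_dim:
            raise ValueError(f"LSTM expects input dim {self.input_dim}, got {D}")
        h = np.zeros((B, self.units))
        C = np.zeros((B, self.units))
        steps = []
        for t in range(T):
            z = np.concatenate([h, x[:, t, :]], axis=1)
            f = _sigmoid(z @ self.Wf.value.T + self.bf.value)
            i = _sigmoid(z @ self.Wi.value.T + self.bi.value)
            c_til = np.tanh(z @ self.Wc.value.T + self.bc.value)
            o = _sigmoid(z @ self.Wo.value.T + self.bo.value)
            C_new = f * C + i * c_til
            tC = np.tanh(C_new)
            h_new = o * tC
            steps.append((z, f, i, c_til, o, C, tC))
            h, C = h_new, C_new
        self._cache = (steps, x.shape)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        steps, x_shape = self._cache
        B, T, D = x_shape
        dx = np.zeros(x_shape)
        dh = dout
        dC = np.zeros_like(dout)
        for t in range(T - 1, -1, -1):
            z, f, i, c_til, o, C_prev, tC = steps[t]
            do = dh * tC
            dC = dC + dh * o * (1.0 - tC**2)
            df = dC * C_prev
            di = dC * c_til
            dc_til = dC * i
            # sigmoid / tanh local derivatives
            dzf = df * f * (1 - f)
            dzi = di * i * (1 - i)
            dzc = dc_til * (1 - c_til**2)
            dzo = do * o * (1 - o)
            self.Wf.grad += dzf.T @ z
            self.Wi.grad += dzi.T @ z
            self.Wc.grad += dzc.T @ z
            self.Wo.grad += dzo.T @ z
            self.bf.grad += dzf.sum(axis=0)
            self.bi.grad += dzi.sum(axis=0)
            self.bc.grad += dzc.sum(axis=0)
            self.bo.grad += dzo.sum(axis=0)
            dz = dzf @ self.Wf.value + dzi @ self.Wi.value + dzc @ self.Wc.value + dzo @ self.Wo.value
            dh = dz[:, : self.units]
            dx[:, t, :] = dz[:, self.units :]
            dC = dC * f
        return dx


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN with a skip connection added before the final ReLU.

    When ``use_skip`` is false the block degenerates to a plain convolutional
    unit (same main path, no addition).  A 1x1 projection convolution carries
    the skip path whenever the channel count or spatial stride changes.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        use_skip: bool = True,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        name: str = "block",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_channels, out_channels, kernel_size, stride, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2d(out_channels, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, kernel_size, 1, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_channels, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.use_skip = use_skip
        self.projection = None
        if use_skip and (in_channels != out_channels or stride != 1):
            self.projection = Conv2d(in_channels, out_channels, 1, stride, rng, f"{name}.proj")

    def params(self) -> list[Param]:
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.projection is not None:
            ps += self.projection.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.conv1.forward(x, train)
        out = self.bn1.forward(out, train)
        out = self.relu1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.bn2.forward(out, train)
        if self.use_skip:
            skip = x if self.projection is None else self.projection.forward(x, train)
            out = out + skip
        return self.relu2.forward(out, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dskip = d if self.use_skip else None
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = self.conv1.backward(d)
        if self.use_skip:
            dx = dx + (dskip if self.projection is None else self.projection.backward(dskip))
        return dx


def softmax_logits(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    probs = softmax_logits(logits)
    B = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(B), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(B), labels] -= 1.0
    return float(loss), grad / B


class SGDM:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Iterable[Param], learning_rate: float, momentum: float = 0.9) -> None:
        self.params = list(params)
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
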