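"""Minimal feed-forward network engine in numpy.

Supports exactly the layer families the window classifiers are built from:
dense layers (automatically time-distributed on 3-D input), 1-D convolution
over the time axis, max pooling, an LSTM returning its final hidden state,
dropout, and flattening — plus SGD / Adam / RMSProp optimizers.  Everything
runs in float64 on CPU; batches are the leading axis.

This is a deliberately small engine: layers expose ``forward``/``backward``
with parameters and gradients in parallel dicts, and a :class:`Network` is an
ordered list of layers ending in a 1-unit linear head whose sigmoid is fused
into the loss for numerical stability.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _activate(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return expit(z)
    if name == "selu":
        return _SELU_LAMBDA * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """d(activation)/dz given pre-activation z and activation a."""
    if name == "linear":
        return np.ones_like(z)
    if name == "tanh":
        return 1.0 - a * a
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "selu":
        return _SELU_LAMBDA * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer; on 3-D input it is applied per time step."""

    def __init__(self, in_features: int, units: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.activation = activation
        self.params = {
            "W": _glorot(rng, (in_features, units), in_features, units),
            "b": np.zeros(units),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._a = _activate(self.activation, self._z)
        return self._a

    def backward(self, dout):
        dz = dout * _activate_grad(self.activation, self._z, self._a)
        x = self._x
        if x.ndim == 3:
            self.grads["W"][...] = np.einsum("bti,btj->ij", x, dz)
            self.grads["b"][...] = dz.sum(axis=(0, 1))
        else:
            self.grads["W"][...] = x.T @ dz
            self.grads["b"][...] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class Conv1D(Layer):
    """Valid 1-D convolution over the time axis of (batch, time, channels)."""

    def __init__(self, in_channels: int, filters: int, kernel: int, activation: str,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.activation = activation
        fan_in = kernel * in_channels
        self.params = {
            "W": _glorot(rng, (kernel, in_channels, filters), fan_in, filters),
            "b": np.zeros(filters),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False, rng=None):
        B, T, C = x.shape
        k = self.kernel
        if T < k:
            raise ValueError(f"input of {T} time steps shorter than conv window {k}")
        self._x = x
        out_T = T - k + 1
        z = np.zeros((B, out_T, self.params["W"].shape[2]))
        for j in range(k):
            z += x[:, j : j + out_T, :] @ self.params["W"][j]
        z += self.params["b"]
        self._z = z
        self._a = _activate(self.activation, z)
        return self._a

    def backward(self, dout):
        dz = dout * _activate_grad(self.activation, self._z, self._a)
        x = self._x
        out_T = dz.shape[1]
        dx = np.zeros_like(x)
        for j in range(self.kernel):
            self.grads["W"][j] = np.einsum("bti,btf->if", x[:, j : j + out_T, :], dz)
            dx[:, j : j + out_T, :] += dz @ self.params["W"][j].T
        self.grads["b"][...] = dz.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    """Max pooling of size ``pool`` over the time axis; trailing remainder dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        B, T, C = x.shape
        out_T = T // self.pool
        if out_T < 1:
            raise ValueError(f"cannot pool {T} time steps with pool size {self.pool}")
        xr = x[:, : out_T * self.pool, :].reshape(B, out_T, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout):
        B, out_T, C = dout.shape
        dx = np.zeros(self._in_shape)
        b, t, c = np.meshgrid(
            np.arange(B), np.arange(out_T), np.arange(C), indexing="ij"
        )
        dx[b, t * self.pool + self._arg, c] = dout
        return dx


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state (batch, units)."""

    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.units = units
        u = units
        self.params = {
            "Wx": _glorot(rng, (in_features, 4 * u), in_features, 4 * u),
            "Wh": _glorot(rng, (u, 4 * u), u, 4 * u),
            "b": np.zeros(4 * u),
        }
        # forget-gate bias at 1 keeps early gradients alive
        self.params["b"][u : 2 * u] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False, rng=None):
        B, T, C = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t, :] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = expit(z[:, :u])
            f = expit(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = expit(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return h

    def backward(self, dout):
        x = self._x
        B, T, C = x.shape
        u = self.units
        for g_ in self.grads.values():
            g_[...] = 0.0
        dh = dout
        dc = np.zeros((B, u))
        dx = np.zeros_like(x)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads["Wx"] += x[:, t, :].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
            dc = dc * f
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Network:
    """An ordered stack of layers ending in a 1-unit linear head.

    ``forward`` returns logits of shape (batch,); ``predict_proba`` applies
    the sigmoid.  The binary cross-entropy gradient with respect to the logit
    is ``(sigmoid(z) - y) / batch``, supplied by the trainer.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int]):
        self.layers = layers
        self.input_shape = input_shape  # (window_length, n_channels)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of shape (batch, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {x.shape}"
            )
        out = x
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return expit(self.forward(x, training=False))

    # --- parameter plumbing -------------------------------------------------
    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (li, name), value, layer.grads[name]

    def get_weights(self) -> dict:
        return {f"{li}.{name}": v.copy() for (li, name), v, _ in self.parameters()}

    def set_weights(self, weights: dict) -> None:
        for (li, name), v, _ in self.parameters():
            v[...] = weights[f"{li}.{name}"]


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, network: Network) -> None:
        for _, value, grad in network.parameters():
            value -= self.lr * grad


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._state: dict = {}
        self._t = 0

    def step(self, network: Network) -> None:
        self._t += 1
        for key, value, grad in network.parameters():
            m, v = self._state.setdefault(
                key, (np.zeros_like(value), np.zeros_like(value))
            )
            m[...] = self.beta1 * m + (1 - self.beta1) * grad
            v[...] = self.beta2 * v + (1 - self.beta2) * grad * grad
            mhat = m / (1 - self.beta1 ** self._t)
            vhat = v / (1 - self.beta2 ** self._t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp:
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._state: dict = {}

    def step(self, network: Network) -> None:
        for key, value, grad in network.parameters():
            v = self._state.setdefault(key, np.zeros_like(value))
            v[...] = self.rho * v + (1 - self.rho) * grad * grad
            value -= self.lr * grad / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, lr: float):
    if name == "sgd":
        return SGD(lr)
    if name == "adam":
        return Adam(lr)
    if name == "rmsprop":
        return RMSProp(lr)
    raise ValueError(f"unknown optimizer {name!r}")
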