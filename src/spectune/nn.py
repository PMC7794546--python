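"""A self-contained numpy backend for training the 1D-CNN regressors.

Implements exactly the layer vocabulary the architecture builder emits —
strided 1-D convolution with Same/Valid padding, batch normalisation,
the five activations (ReLU, LeakyReLU, ELU, SELU, Swish), average/max
pooling, inverted dropout, flatten and dense layers — together with the
three mini-batch optimisers (Adagrad, RMSProp, Adam) and an early-stopping
training loop that restores the best weights.

All forward/backward passes are vectorised; inputs are channels-first
(n, channels, width). Gradients are verified against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .builder import ArchitectureSpec

__all__ = [
    "Network",
    "Predictor",
    "TrainingDivergedError",
    "build_network",
    "make_optimiser",
    "train_network",
    "DEFAULT_LEARNING_RATES",
]

#: Backend default learning rate per optimiser (recorded in run metadata).
DEFAULT_LEARNING_RATES = {"Adagrad": 1e-2, "RMSProp": 1e-3, "Adam": 1e-3}

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


class TrainingDivergedError(RuntimeError):
    """Raised when a loss or monitored metric becomes non-finite."""


def _same_pad(w_in: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-w_in // stride)
    pad = max((out - 1) * stride + kernel - w_in, 0)
    return pad // 2, pad - pad // 2


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Arrays to snapshot/restore (weights plus e.g. BN running stats)."""
        return [p for p, _ in self.params_grads()]


class Conv1D(Layer):
    def __init__(self, in_c: int, out_c: int, kernel: int, stride: int, padding: str, rng):
        std = np.sqrt(1.0 / (in_c * kernel))  # LeCun normal (SELU-compatible)
        self.W = rng.normal(0.0, std, size=(out_c, in_c, kernel))
        self.b = np.zeros(out_c)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, training):
        if self.padding == "Same":
            pl, pr = _same_pad(x.shape[2], self.kernel, self.stride)
        else:
            pl = pr = 0
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride, :]
        self._win = win
        self._pl, self._w_in, self._wp = pl, x.shape[2], xp.shape[2]
        return np.einsum("ock,ncwk->now", self.W, win, optimize=True) + self.b[None, :, None]

    def backward(self, grad):
        self.dW = np.einsum("now,ncwk->ock", grad, self._win, optimize=True)
        self.db = grad.sum(axis=(0, 2))
        n, _, out_w = grad.shape
        dxp = np.zeros((n, self.W.shape[1], self._wp))
        for kk in range(self.kernel):
            contrib = np.einsum("now,oc->ncw", grad, self.W[:, :, kk], optimize=True)
            dxp[:, :, kk : kk + self.stride * out_w : self.stride] += contrib
        return dxp[:, :, self._pl : self._pl + self._w_in]

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm(Layer):
    """Normalises per channel (conv input, over sample and width axes) or per
    feature (dense input, over the sample axis)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps

    def _axes_shape(self, x):
        if x.ndim == 3:
            return (0, 2), (1, -1, 1)
        return (0,), (1, -1)

    def forward(self, x, training):
        axes, shp = self._axes_shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        if training:
            self._xhat, self._inv, self._axes, self._shp = xhat, inv, axes, shp
            self._m = x.size // x.shape[1] if x.ndim == 3 else x.shape[0]
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, grad):
        axes, shp = self._axes, self._shp
        self.dgamma = (grad * self._xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        m = self._m
        g = self.gamma.reshape(shp) * self._inv.reshape(shp)
        return g * (
            grad
            - self.dbeta.reshape(shp) / m
            - self._xhat * self.dgamma.reshape(shp) / m
        )

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state_arrays(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Activation(Layer):
    def __init__(self, name: str, leaky_slope: float = 0.01):
        self.name = name
        self.leaky_slope = leaky_slope
        if name not in ("ReLU", "LeakyReLU", "ELU", "SELU", "Swish", "Linear"):
            raise ValueError(f"unknown activation {name!r}")

    def forward(self, x, training):
        self._x = x
        n = self.name
        if n == "ReLU":
            return np.maximum(x, 0.0)
        if n == "LeakyReLU":
            return np.where(x > 0, x, self.leaky_slope * x)
        if n == "ELU":
            return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        if n == "SELU":
            return _SELU_LAMBDA * np.where(
                x > 0, x, _SELU_ALPHA * np.expm1(np.minimum(x, 0.0))
            )
        if n == "Swish":
            s = _sigmoid(x)
            self._s = s
            return x * s
        return x  # Linear

    def backward(self, grad):
        x = self._x
        n = self.name
        if n == "ReLU":
            return grad * (x > 0)
        if n == "LeakyReLU":
            return grad * np.where(x > 0, 1.0, self.leaky_slope)
        if n == "ELU":
            return grad * np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))
        if n == "SELU":
            return grad * _SELU_LAMBDA * np.where(
                x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0))
            )
        if n == "Swish":
            s = self._s
            return grad * (s + x * s * (1.0 - s))
        return grad


class Pool1D(Layer):
    def __init__(self, kind: str, size: int, stride: int, padding: str):
        if kind not in ("Average", "Max"):
            raise ValueError(f"unknown pooling type {kind!r}")
        self.kind, self.size, self.stride, self.padding = kind, size, stride, padding

    def forward(self, x, training):
        if self.padding == "Same":
            pl, pr = _same_pad(x.shape[2], self.size, self.stride)
        else:
            pl = pr = 0
        fill = -np.inf if self.kind == "Max" else 0.0
        xp = (
            np.pad(x, ((0, 0), (0, 0), (pl, pr)), constant_values=fill) if (pl or pr) else x
        )
        win = sliding_window_view(xp, self.size, axis=2)[:, :, :: self.stride, :]
        self._pl, self._w_in, self._wp = pl, x.shape[2], xp.shape[2]
        self._out_w = win.shape[2]
        if self.kind == "Max":
            self._arg = np.argmax(win, axis=3)
            return np.max(win, axis=3)
        return win.mean(axis=3)

    def backward(self, grad):
        n, c, out_w = grad.shape
        dxp = np.zeros((n, c, self._wp))
        if self.kind == "Max":
            ni, ci, wi = np.indices(grad.shape)
            np.add.at(dxp, (ni, ci, wi * self.stride + self._arg), grad)
        else:
            g = grad / self.size
            for kk in range(self.size):
                dxp[:, :, kk : kk + self.stride * out_w : self.stride] += g
        return dxp[:, :, self._pl : self._pl + self._w_in]


class Dropout(Layer):
    """Inverted dropout; `rate` is the probability of zeroing a unit."""

    def __init__(self, rate: float, rng):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng):
        std = np.sqrt(1.0 / in_features)
        self.W = rng.normal(0.0, std, size=(in_features, units))
        self.b = np.zeros(units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False).ravel()

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for layer in self.layers for a in layer.state_arrays()]

    def restore(self, snap: list[np.ndarray]) -> None:
        arrays = [a for layer in self.layers for a in layer.state_arrays()]
        for a, s in zip(arrays, snap, strict=True):
            a[...] = s


def build_network(arch: ArchitectureSpec, rng: np.random.Generator) -> Network:
    """Instantiate the layer stack an ArchitectureSpec describes."""
    layers: list[Layer] = []
    ch = arch.input_channels
    in_dense = None
    for ly in arch.layers:
        t = ly.layer_type
        if t == "convolutional":
            layers.append(
                Conv1D(ch, ly.params["filters"], ly.params["kernel"], ly.params["stride"],
                       ly.params["padding"], rng)
            )
            ch = ly.params["filters"]
        elif t == "batch_norm":
            layers.append(BatchNorm(ch if in_dense is None else ly.output_width))
        elif t == "activation":
            layers.append(Activation(ly.params["activation"]))
        elif t == "pooling":
            layers.append(
                Pool1D(ly.params["pool_type"], ly.params["pool_size"], ly.params["stride"],
                       ly.params["padding"])
            )
        elif t == "dropout":
            layers.append(Dropout(ly.params["rate"], rng))
        elif t == "flatten":
            layers.append(Flatten())
            in_dense = ly.output_width
        elif t == "dense":
            layers.append(Dense(in_dense, ly.params["units"], rng))
            in_dense = ly.params["units"]
        else:  # pragma: no cover
            raise ValueError(f"unknown layer type {t!r}")
    return Network(layers)


# ---------------------------------------------------------------------------
# optimisers
# ---------------------------------------------------------------------------


class _Optimiser:
    def __init__(self, lr: float, eps: float = 1e-8):
        self.lr, self.eps = lr, eps
        self._state: dict[int, dict] = {}

    def _slot(self, param: np.ndarray) -> dict:
        key = id(param)
        if key not in self._state:
            self._state[key] = self._init_slot(param)
        return self._state[key]

    def step(self, params_grads) -> None:
        for p, g in params_grads:
            self._update(p, g, self._slot(p))


class Adagrad(_Optimiser):
    def _init_slot(self, p):
        return {"acc": np.zeros_like(p)}

    def _update(self, p, g, s):
        s["acc"] += g * g
        p -= self.lr * g / (np.sqrt(s["acc"]) + self.eps)


class RMSProp(_Optimiser):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(lr, eps)
        self.rho = rho

    def _init_slot(self, p):
        return {"acc": np.zeros_like(p)}

    def _update(self, p, g, s):
        s["acc"] = self.rho * s["acc"] + (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(s["acc"]) + self.eps)


class Adam(_Optimiser):
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(lr, eps)
        self.beta1, self.beta2 = beta1, beta2

    def _init_slot(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p), "t": 0}

    def _update(self, p, g, s):
        s["t"] += 1
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
        mhat = s["m"] / (1 - self.beta1 ** s["t"])
        vhat = s["v"] / (1 - self.beta2 ** s["t"])
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimiser(name: str, learning_rate: float | None = None) -> _Optimiser:
    lr = DEFAULT_LEARNING_RATES[name] if learning_rate is None else learning_rate
    if name == "Adagrad":
        return Adagrad(lr)
    if name == "RMSProp":
        return RMSProp(lr)
    if name == "Adam":
        return Adam(lr)
    raise ValueError(f"unknown optimiser {name!r}")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


class Predictor:
    """Trained-model handle: maps channels-first input arrays to estimates."""

    def __init__(self, network: Network, epochs_run: int):
        self.network = network
        self.epochs_run = epochs_run

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict(x)


def train_network(
    network: Network,
    optimiser_name: str,
    batch_size: int,
    max_epochs: int,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_monitor: np.ndarray,
    y_monitor: np.ndarray,
    rng: np.random.Generator,
    patience: int = 50,
    min_delta: float = 0.0,
    learning_rate: float | None = None,
) -> Predictor:
    """Mini-batch MSE training with early stopping on a monitor partition.

    Stops at max_epochs or when the monitor MSE has not improved by min_delta
    for `patience` consecutive epochs; the best-epoch weights are restored.
    Raises TrainingDivergedError on a non-finite loss.
    """
    if max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    n = x_train.shape[0]
    batch_size = max(1, min(batch_size, n))
    opt = make_optimiser(optimiser_name, learning_rate)
    best = np.inf
    best_snap = network.snapshot()
    wait = 0
    epochs_run = 0
    for _epoch in range(max_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = network.forward(xb, training=True).ravel()
            resid = pred - yb
            with np.errstate(over="ignore"):
                loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError("non-finite training loss")
            grad = (2.0 * resid / len(yb)).reshape(-1, 1)
            network.backward(grad)
            opt.step(network.params_grads())
        epochs_run += 1
        mon_pred = network.predict(x_monitor)
        mon_mse = float(np.mean((mon_pred - y_monitor) ** 2))
        if not np.isfinite(mon_mse):
            raise TrainingDivergedError("non-finite monitor loss")
        if mon_mse < best - min_delta:
            best = mon_mse
            best_snap = network.snapshot()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    network.restore(best_snap)
    return Predictor(network, epochs_run)
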