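"""Compact NumPy neural-network engine for 1-D convolutional classifiers.

Implements exactly the layer set the grouped-convolution architecture
needs — grouped 1-D convolution with 'same' padding, pointwise (1x1)
convolution, max-pooling, inverted dropout, dense layers, the activation
functions tanh/sigmoid/relu/leaky_relu/elu/selu — together with reverse-
mode gradients and the SGD and Adam optimisers. Everything is float64 and
deterministic given a seed, so fitted weights are bit-reproducible on a
single thread.

Layers follow the usual forward/backward contract: ``forward(x, train)``
caches what backward needs; ``backward(grad_out)`` accumulates parameter
gradients in ``layer.grads`` and returns the gradient w.r.t. the input.
Data layout is (batch, channels, length) for convolutional layers.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigError

# ---------------------------------------------------------------------------
# activations

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805

ACTIVATIONS = ("tanh", "sigmoid", "relu", "leaky_relu", "elu", "selu")


def _act_forward(kind: str, x: np.ndarray) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(x)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "leaky_relu":
        return np.where(x > 0, x, 0.01 * x)
    if kind == "elu":
        return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    if kind == "selu":
        return _SELU_SCALE * np.where(
            x > 0, x, _SELU_ALPHA * np.expm1(np.minimum(x, 0.0))
        )
    raise ConfigError(f"unknown activation {kind!r}; choose from {ACTIVATIONS}")


def _act_grad(kind: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(activation)/dx given input x and output y."""
    if kind == "tanh":
        return 1.0 - y * y
    if kind == "sigmoid":
        return y * (1.0 - y)
    if kind == "relu":
        return (x > 0).astype(x.dtype)
    if kind == "leaky_relu":
        return np.where(x > 0, 1.0, 0.01)
    if kind == "elu":
        return np.where(x > 0, 1.0, y + 1.0)
    if kind == "selu":
        return np.where(x > 0, _SELU_SCALE, y + _SELU_SCALE * _SELU_ALPHA)
    raise ConfigError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: parameter and gradient dicts, no-op state."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Layer):
    """Grouped 1-D convolution, 'same' padding, stride 1.

    Output channels are split into ``groups`` partitions. Each partition
    sees its slice of the input channels (in_channels / groups of them);
    when the layer sits on a single-channel input, channel splitting is
    impossible and every partition convolves the whole input instead —
    the grouping is then organisational and does not reduce parameters,
    which is why the parameter saving of grouping shows up from the second
    of two consecutive grouped layers onwards.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        groups: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ConfigError(f"{name}: kernel size must be odd for same padding")
        if out_channels % groups != 0:
            raise ConfigError(
                f"{name}: {out_channels} output channels not divisible "
                f"into {groups} groups"
            )
        if in_channels > 1 and in_channels % groups != 0:
            raise ConfigError(
                f"{name}: {in_channels} input channels not divisible "
                f"into {groups} groups"
            )
        self.name = name
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.groups = groups
        # channels each partition actually sees
        self.group_in = in_channels if in_channels == 1 else in_channels // groups
        self.group_out = out_channels // groups
        rng = rng or np.random.default_rng()
        fan_in = self.group_in * kernel_size
        self.params["weight"] = _fan_in_uniform(
            rng, (out_channels, self.group_in, kernel_size), fan_in
        )
        self.params["bias"] = np.zeros(out_channels)
        self._cache: tuple | None = None

    @property
    def weight_count(self) -> int:
        """Number of multiplicative weights (biases excluded)."""
        return self.out_channels * self.group_in * self.kernel_size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C, L) -> columns (B, C, k, L) with same padding
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        length = x.shape[2]
        return np.stack([xp[:, :, i : i + length] for i in range(k)], axis=2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = self._im2col(x)  # (B, C, k, L)
        w = self.params["weight"]
        outs = []
        for g in range(self.groups):
            wg = w[g * self.group_out : (g + 1) * self.group_out]
            if self.in_channels == 1:
                cg = cols
            else:
                cg = cols[:, g * self.group_in : (g + 1) * self.group_in]
            outs.append(np.einsum("ock,bckl->bol", wg, cg, optimize=True))
        y = np.concatenate(outs, axis=1) + self.params["bias"][None, :, None]
        self._cache = (x.shape, cols)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        w = self.params["weight"]
        k = self.kernel_size
        pad = k // 2
        length = x_shape[2]
        dw = np.empty_like(w)
        dcols = np.zeros_like(cols)
        for g in range(self.groups):
            sl = slice(g * self.group_out, (g + 1) * self.group_out)
            gg = grad[:, sl]
            if self.in_channels == 1:
                cg = cols
            else:
                cg = cols[:, g * self.group_in : (g + 1) * self.group_in]
            dw[sl] = np.einsum("bol,bckl->ock", gg, cg, optimize=True)
            dcg = np.einsum("ock,bol->bckl", w[sl], gg, optimize=True)
            if self.in_channels == 1:
                dcols += dcg
            else:
                dcols[:, g * self.group_in : (g + 1) * self.group_in] = dcg
        self.grads["weight"] = dw
        self.grads["bias"] = grad.sum(axis=(0, 2))
        # fold the column gradient back onto the padded input
        dxp = np.zeros((x_shape[0], x_shape[1], length + 2 * pad))
        for i in range(k):
            dxp[:, :, i : i + length] += dcols[:, :, i]
        return dxp[:, :, pad : pad + length]


class Activation(Layer):
    def __init__(self, kind: str) -> None:
        super().__init__()
        if kind not in ACTIVATIONS:
            raise ConfigError(f"unknown activation {kind!r}; choose from {ACTIVATIONS}")
        self.kind = kind
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = _act_forward(self.kind, x)
        self._cache = (x, y)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, y = self._cache
        return grad * _act_grad(self.kind, x, y)


class MaxPool1d(Layer):
    """Non-overlapping max-pooling; trailing remainder positions dropped."""

    def __init__(self, pool_size: int) -> None:
        super().__init__()
        if pool_size < 1:
            raise ConfigError("pool size must be >= 1")
        self.pool_size = pool_size
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, length = x.shape
        p = self.pool_size
        out_len = length // p
        if out_len < 1:
            raise ConfigError(f"pooled length {out_len} < 1 for input length {length}")
        xw = x[:, :, : out_len * p].reshape(b, c, out_len, p)
        idx = xw.argmax(axis=3)
        self._cache = (x.shape, idx)
        return np.take_along_axis(xw, idx[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, idx = self._cache
        b, c, length = x_shape
        p = self.pool_size
        out_len = length // p
        dxw = np.zeros((b, c, out_len, p))
        np.put_along_axis(dxw, idx[..., None], grad[..., None], axis=3)
        dx = np.zeros(x_shape)
        dx[:, :, : out_len * p] = dxw.reshape(b, c, out_len * p)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ConfigError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["weight"] = _fan_in_uniform(
            rng, (in_features, out_features), in_features
        )
        self.params["bias"] = np.zeros(out_features)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["weight"] = self._x.T @ grad
        self.grads["bias"] = grad.sum(axis=0)
        return grad @ self.params["weight"].T


class Sequential:
    """A plain layer stack with reverse-order backpropagation."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, k) for layer in self.layers for k in layer.params]

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping for serialisation."""
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"layer{i:02d}.{k}"] = v
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = np.asarray(arrays[f"layer{i:02d}.{k}"])


# ---------------------------------------------------------------------------
# optimisers


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params: list[tuple[Layer, str]], lr: float) -> None:
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for layer, key in self.params:
            layer.params[key] -= self.lr * layer.grads[key]


class Adam:
    """Adam with conventional moment defaults (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: list[tuple[Layer, str]],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in params]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, key) in enumerate(self.params):
            g = layer.grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, params: list[tuple[Layer, str]], lr: float):
    if name == "Adam":
        return Adam(params, lr)
    if name == "SGD":
        return SGD(params, lr)
    raise ConfigError(f"unknown optimizer {name!r}; choose Adam or SGD")
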