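"""Minimal CNN engine for coordinate regression.

Implements exactly the layer vocabulary the cascade architectures use —
valid 2-D convolution, non-overlapping max pooling (floor or ceiling
division), dropout, ReLU and fully connected layers — together with the
reverse-mode gradients of the mean-squared-error objective and the Adadelta
update rule.  Arrays are NHWC float64/float32; convolution is evaluated as a
batched tensor contraction over sliding windows so the heavy lifting lands
in BLAS.

Nothing here is specific to spines; :mod:`spinealign.models` builds networks
from declarative architecture specs on top of these primitives.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "MaxPool2D", "Dropout", "ReLU", "Flatten", "Dense",
    "Network", "Adadelta", "mse_loss", "mse_grad",
]

# cap on the materialized sliding-window tensor (float32 elements)
_WINDOW_CHUNK_ELEMS = 16_000_000


def mse_loss(outputs: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared error L = (1/n) sum (A_j - Y_j)^2 over all n elements."""
    outputs = np.asarray(outputs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if outputs.shape != labels.shape:
        raise ValueError(f"shape mismatch: {outputs.shape} vs {labels.shape}")
    d = outputs - labels
    return float(np.mean(d * d))


def mse_grad(outputs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return 2.0 * (outputs - labels) / outputs.size


class Layer:
    """Base layer: parameter dicts plus forward/backward passes."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _windows(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # (N, H', W', C, kh, kw) view over NHWC input
    return sliding_window_view(x, (kh, kw), axis=(1, 2))


class Conv2D(Layer):
    """Valid (unpadded) convolution, stride 1, NHWC."""

    def __init__(self, in_channels: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator, gain: float = 1.0) -> None:
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * in_channels
        self.kernel = (kh, kw)
        # gain 1 (Xavier) for linear conv stacks, sqrt(2) (He) when the conv
        # is followed by a ReLU: keeps unit-variance propagation either way
        self.params["w"] = rng.normal(
            0.0, gain * np.sqrt(1.0 / fan_in), size=(kh, kw, in_channels, filters)
        ).astype(np.float32)
        self.params["b"] = np.zeros(filters, dtype=np.float32)
        self.input_layer = False  # set True to skip the input gradient
        self._x: np.ndarray | None = None

    #: below this C*kh*kw, a single im2col GEMM beats the per-tap loop
    _IM2COL_MAX = 64

    def _cols(self, x: np.ndarray, ho: int, wo: int) -> np.ndarray:
        kh, kw = self.kernel
        # (N, Ho, Wo, C, kh, kw) -> (N*Ho*Wo, kh*kw*C) matching w layout
        win = _windows(x, kh, kw)
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            x.shape[0] * ho * wo, -1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kh, kw = self.kernel
        self._x = x
        n, h, w, c = x.shape
        ho, wo = h - kh + 1, w - kw + 1
        wgt = self.params["w"]
        f = wgt.shape[-1]
        if c * kh * kw <= self._IM2COL_MAX:
            out = (self._cols(x, ho, wo) @ wgt.reshape(-1, f)).reshape(n, ho, wo, f)
        else:
            # shift-and-accumulate: one (N*Ho*Wo, C) @ (C, F) GEMM per tap,
            # avoiding the kh*kw-fold im2col tensor
            out = np.zeros((n, ho, wo, f), dtype=np.result_type(x, wgt))
            flat = out.reshape(-1, f)
            for dy in range(kh):
                for dx in range(kw):
                    sl = x[:, dy:dy + ho, dx:dx + wo, :].reshape(-1, c)
                    flat += sl @ wgt[dy, dx]
        out += self.params["b"]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        x = self._x
        assert x is not None
        n, h, w, c = x.shape
        ho, wo = g.shape[1], g.shape[2]
        wgt = self.params["w"]
        f = wgt.shape[-1]
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        gflat = g.reshape(-1, f)

        if c * kh * kw <= self._IM2COL_MAX:
            gw = (self._cols(x, ho, wo).T @ gflat).reshape(kh, kw, c, f)
            self.grads["w"] = gw
            if self.input_layer:
                return np.zeros_like(x)
            gx = np.zeros_like(x, dtype=np.result_type(g, wgt))
            for dy in range(kh):
                for dx in range(kw):
                    gx[:, dy:dy + ho, dx:dx + wo, :] += (
                        gflat @ wgt[dy, dx].T).reshape(n, ho, wo, c)
            return gx

        gw = np.empty_like(wgt)
        gx = None if self.input_layer else np.zeros_like(
            x, dtype=np.result_type(g, wgt))
        for dy in range(kh):
            for dx in range(kw):
                sl = x[:, dy:dy + ho, dx:dx + wo, :].reshape(-1, c)
                gw[dy, dx] = sl.T @ gflat
                if gx is not None:
                    gx[:, dy:dy + ho, dx:dx + wo, :] += (
                        gflat @ wgt[dy, dx].T).reshape(n, ho, wo, c)
        self.grads["w"] = gw
        return np.zeros_like(x) if gx is None else gx


class MaxPool2D(Layer):
    """Non-overlapping max pooling; floor division by default, optional
    ceiling mode (pads partial cells with -inf)."""

    def __init__(self, pool: tuple[int, int], ceil: bool = False) -> None:
        super().__init__()
        self.pool = pool
        self.ceil = ceil
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        ph, pw = self.pool
        if self.ceil:
            return -(-h // ph), -(-w // pw)
        return h // ph, w // pw

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        ph, pw = self.pool
        n, h, w, c = x.shape
        ho, wo = self.out_hw(h, w)
        self._in_shape = x.shape
        if self.ceil:
            x = np.pad(x, ((0, 0), (0, ho * ph - h), (0, wo * pw - w), (0, 0)),
                       constant_values=-np.inf)
        else:
            x = x[:, : ho * ph, : wo * pw]
        cells = x.reshape(n, ho, ph, wo, pw, c).transpose(0, 1, 3, 5, 2, 4)
        cells = cells.reshape(n, ho, wo, c, ph * pw)
        self._argmax = cells.argmax(axis=-1)
        return cells.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        ph, pw = self.pool
        n, h, w, c = self._in_shape  # type: ignore[misc]
        ho, wo = self.out_hw(h, w)
        flat = np.zeros((n, ho, wo, c, ph * pw), dtype=g.dtype)
        np.put_along_axis(flat, self._argmax[..., None], g[..., None], axis=-1)
        full = flat.reshape(n, ho, wo, c, ph, pw).transpose(0, 1, 4, 2, 5, 3)
        full = full.reshape(n, ho * ph, wo * pw, c)
        gx = np.zeros((n, h, w, c), dtype=g.dtype)
        hh, ww = min(h, ho * ph), min(w, wo * pw)
        gx[:, :hh, :ww] = full[:, :hh, :ww]
        return gx


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = rng.normal(
            0.0, np.sqrt(1.0 / in_features), size=(in_features, units)
        ).astype(np.float32)
        self.params["b"] = np.zeros(units, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["w"].T


class Network:
    """A plain sequential network over the layers above."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, k) for layer in self.layers for k in layer.params]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"layer{i:02d}_{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                arr = state[f"layer{i:02d}_{k}"]
                if arr.shape != layer.params[k].shape:
                    raise ValueError(f"shape mismatch for layer{i:02d}_{k}")
                layer.params[k] = arr.astype(np.float32)


class Adadelta:
    """Adadelta (Zeiler 2012): per-parameter adaptive learning rates from
    running averages of squared gradients and squared updates."""

    def __init__(self, network: Network, rho: float = 0.9, eps: float = 1e-6,
                 lr: float = 1.0) -> None:
        self.network = network
        self.rho = rho
        self.eps = eps
        self.lr = lr
        self._eg2: dict[tuple[int, str], np.ndarray] = {}
        self._ed2: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        for idx, (layer, key) in enumerate(self.network.parameters()):
            g = layer.grads.get(key)
            if g is None:
                continue
            g = g.astype(layer.params[key].dtype)
            sk = (idx, key)
            if sk not in self._eg2:
                self._eg2[sk] = np.zeros_like(g)
                self._ed2[sk] = np.zeros_like(g)
            eg2, ed2 = self._eg2[sk], self._ed2[sk]
            eg2 *= self.rho
            eg2 += (1.0 - self.rho) * g * g
            dx = -np.sqrt(ed2 + self.eps) / np.sqrt(eg2 + self.eps) * g
            ed2 *= self.rho
            ed2 += (1.0 - self.rho) * dx * dx
            layer.params[key] = layer.params[key] + self.lr * dx
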