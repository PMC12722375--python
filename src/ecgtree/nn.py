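"""Minimal numpy neural-network layers with hand-written backprop.

Supports exactly what the convolutional beta-VAE needs: 1-D same-padding
convolutions (via sliding-window im2col + BLAS matmul), ReLU, max pooling and
nearest-neighbour upsampling by 2, dense layers, and Adam.  All computation is
float32; every source of randomness takes an explicit Generator.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padding stride-1 1-D convolution over (B, C, L) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in * k))
        self.params = [w.astype(np.float32), np.zeros(c_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        bsz, c, ln = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (B, C, L, k) view -> (B*L, C*k) matrix
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(bsz * ln, c * self.k)
        self._cols, self._shape = cols, (bsz, c, ln)
        y = cols @ w.T + b
        return np.ascontiguousarray(
            y.reshape(bsz, ln, self.c_out).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        bsz, c, ln = self._shape
        dyr = dy.transpose(0, 2, 1).reshape(bsz * ln, self.c_out)
        self.grads[0] += dyr.T @ self._cols
        self.grads[1] += dyr.sum(axis=0)
        dcols = (dyr @ w).reshape(bsz, ln, c, self.k)
        pad = self.k // 2
        dxp = np.zeros((bsz, c, ln + 2 * pad), dtype=np.float32)
        for j in range(self.k):
            dxp[:, :, j:j + ln] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad:pad + ln]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """Max pooling with window/stride 2 (length must be even)."""

    def forward(self, x):
        bsz, c, ln = x.shape
        xr = x.reshape(bsz, c, ln // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, dy):
        bsz, c, ln = self._shape
        dxr = np.zeros((bsz, c, ln // 2, 2), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        return dxr.reshape(bsz, c, ln)


class Upsample2(Layer):
    """Nearest-neighbour upsampling by 2 along the time axis."""

    def forward(self, x):
        return np.repeat(x, 2, axis=2)

    def backward(self, dy):
        bsz, c, ln = dy.shape
        return dy.reshape(bsz, c, ln // 2, 2).sum(axis=3)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.params = [w.astype(np.float32), np.zeros(n_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x):
        self._x = x
        w, b = self.params
        return x @ w.T + b

    def backward(self, dy):
        w, _ = self.params
        self.grads[0] += dy.T @ self._x
        self.grads[1] += dy.sum(axis=0)
        return dy @ w


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    @property
    def param_layers(self):
        return [l for l in self.layers if l.params]

    def n_params(self) -> int:
        return sum(p.size for l in self.layers for p in l.params)


class Adam:
    def __init__(self, modules: list[Sequential], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = []
        for mod in modules:
            for layer in mod.param_layers:
                for p, g in zip(layer.params, layer.grads):
                    self.slots.append((p, g, np.zeros_like(p), np.zeros_like(p)))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for _, g, _, _ in self.slots:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in self.slots:
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
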