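"""A small CNN implemented in NumPy with an Adam optimizer.

Three conv/relu/maxpool blocks, global average pooling and a softmax head.
Runs on CPU at desk scale; the backbone registry lets a larger architecture
be plugged in without changing the training code.
"""

from __future__ import annotations

import numpy as np

ADAM_BETA2 = 0.999


class _Conv3x3:
    """'Same' 3x3 convolution computed as nine shifted tensor contractions."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)

    def forward(self, x):
        n, c, h, w = x.shape
        self._xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._x_shape = x.shape
        out = np.zeros((n, self.w.shape[0], h, w))
        for i in range(3):
            for j in range(3):
                # (N,C,H,W) x (O,C) -> accumulate into (N,O,H,W)
                out += np.tensordot(
                    self._xp[:, :, i:i + h, j:j + w], self.w[:, :, i, j],
                    axes=([1], [1]),
                ).transpose(0, 3, 1, 2)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        n, c, h, w = self._x_shape
        self.dw = np.empty_like(self.w)
        dxp = np.zeros_like(self._xp)
        for i in range(3):
            for j in range(3):
                xs = self._xp[:, :, i:i + h, j:j + w]
                self.dw[:, :, i, j] = np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i:i + h, j:j + w] += np.tensordot(
                    dout, self.w[:, :, i, j], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.db = dout.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:1 + h, 1:1 + w]

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._x_shape
        dr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dr, self._argmax[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)

    def params(self):
        return []


class _GlobalAvgPool:
    def forward(self, x):
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._x_shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)

    def params(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class TinyCnn:
    """3-block CNN for unit-scale RGB tiles resized to ``input_px``."""

    input_px = 64

    def __init__(self, seed: int = 0, n_classes: int = 2,
                 channels: tuple[int, ...] = (8, 16, 32)):
        rng = np.random.default_rng(seed)
        self.channels = channels
        c_prev = 3
        self.layers = []
        for c in channels:
            self.layers += [_Conv3x3(c_prev, c, rng), _ReLU(), _MaxPool2()]
            c_prev = c
        self.layers += [_GlobalAvgPool(), _Dense(c_prev, n_classes, rng)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, input_px, input_px, 3) unit-scale -> logits (N, n_classes)."""
        out = np.ascontiguousarray((x - 0.5).transpose(0, 3, 1, 2))
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def parameters(self):
        for layer in self.layers:
            yield from layer.params()

    def state(self) -> dict:
        return {f"{i}.{name}": arr.copy() for i, layer in enumerate(self.layers)
                for name, arr, _ in _param_views(layer)}

    def load_state(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr, _ in _param_views(layer):
                arr[...] = state[f"{i}.{name}"]


def _param_views(layer):
    for name in ("w", "b"):
        if hasattr(layer, name):
            yield name, getattr(layer, name), None


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with the configured momentum (beta1) and epsilon."""

    def __init__(self, model: TinyCnn, lr: float, beta1: float = 0.9,
                 beta2: float = ADAM_BETA2, eps: float = 1e-7):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for idx, (_, param, grad) in enumerate(self.model.parameters()):
            m = self._m.setdefault(idx, np.zeros_like(param))
            v = self._v.setdefault(idx, np.zeros_like(param))
            m[...] = self.beta1 * m + (1 - self.beta1) * grad
            v[...] = self.beta2 * v + (1 - self.beta2) * grad**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


BACKBONES = {"tiny_cnn": TinyCnn}
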