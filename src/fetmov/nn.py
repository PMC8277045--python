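"""A compact numpy convolutional network with minibatch SGD.

Exactly what the classifier needs, nothing more: valid (unpadded) 2-D
convolutions via im2col + matmul, ReLU, a dense softmax head, softmax
cross-entropy, and plain SGD.  Forward/backward passes are deterministic
given the init/shuffle seed, which the pipeline's reproducibility contract
relies on.  Arrays are NCHW float64 at the API surface, float32 internally
for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Conv2D", "ReLU", "Flatten", "Dense", "Sequential",
           "softmax", "cross_entropy"]


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sgd_step(self, lr: float) -> None:
        pass

    @property
    def n_params(self) -> int:
        return 0

    def params(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Valid 2-D convolution (cross-correlation), weight shape (F, C, kh, kw)."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator):
        self.c, self.f = in_channels, out_channels
        self.kh, self.kw = kernel
        fan_in = self.c * self.kh * self.kw
        # He init, suited to the ReLU nonlinearity that follows
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(self.f, fan_in)).astype(np.float32)
        self.b = np.zeros(self.f, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        oh, ow = h - self.kh + 1, w - self.kw + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"input {h}x{w} smaller than kernel {self.kh}x{self.kw}"
            )
        return oh, ow

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self.out_shape(h, w)
        win = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw),
                                                       axis=(2, 3))
        # (n, c, oh, ow, kh, kw) -> (n, oh, ow, c*kh*kw)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, -1)
        return np.ascontiguousarray(col)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c:
            raise ValueError(f"expected {self.c} input channels, got {c}")
        oh, ow = self.out_shape(h, w)
        col = self._im2col(x)
        out = col.reshape(-1, col.shape[-1]) @ self.w.T + self.b
        out = out.reshape(n, oh, ow, self.f).transpose(0, 3, 1, 2)
        if train:
            self._cache = (col, (n, c, h, w))
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        col, (n, c, h, w) = self._cache
        f = self.f
        oh, ow = grad.shape[2], grad.shape[3]
        g = grad.transpose(0, 2, 3, 1).reshape(-1, f).astype(np.float32)
        flat = col.reshape(-1, col.shape[-1])
        self.gw = (g.T @ flat) / n
        self.gb = g.sum(axis=0) / n
        dcol = (g @ self.w).reshape(n, oh, ow, c, self.kh, self.kw)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i : i + oh, j : j + ow] += dcol[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dx

    def sgd_step(self, lr: float) -> None:
        self.w -= lr * self.gw
        self.b -= lr * self.gb

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.gw = self._x.T @ grad / n
        self.gb = grad.sum(axis=0) / n
        return grad @ self.w.T

    def sgd_step(self, lr: float) -> None:
        self.w -= lr * self.gw
        self.b -= lr * self.gb

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


@dataclass
class Sequential:
    layers: list[Layer] = field(default_factory=list)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False).astype(np.float64))

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One SGD step on a minibatch; returns the batch mean CE loss."""
        logits = self.forward(x, train=True)
        probs = softmax(logits.astype(np.float64))
        loss = cross_entropy(probs, y)
        if not np.isfinite(loss):
            raise FloatingPointError("training loss is not finite")
        grad = probs.copy()
        grad[np.arange(len(y)), y] -= 1.0
        grad = grad.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for layer in self.layers:
            layer.sgd_step(lr)
        return loss

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]
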