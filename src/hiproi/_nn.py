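"""Minimal NumPy convolutional-network machinery for the detector.

Implements just what the single-feature-layer detector needs: strided 3x3
convolutions with explicit backward passes (computed as k*k sliced
tensordots so the heavy lifting stays in BLAS), ReLU, and Adam.  Arrays are
float32 throughout; all randomness comes from a caller-supplied Generator,
so training is bit-reproducible for a fixed seed on one device.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "Sequential", "Adam"]


class Conv2d:
    """2-D convolution, square kernel, same-style zero padding.

    He-normal weight init; ``bias_init`` may be a scalar or a per-channel
    array (used to bias the background class at the head).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        ksize: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
        bias_init: float | np.ndarray = 0.0,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.stride = int(stride)
        self.pad = int(pad)
        self.ksize = int(ksize)
        he = np.sqrt(2.0 / (c_in * ksize * ksize))
        self.weight = rng.normal(0.0, he, size=(c_out, c_in, ksize, ksize)).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32) + np.asarray(bias_init, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._x_pad: np.ndarray | None = None

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.ksize, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, _, h, w = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        oh, ow = self.out_hw(h, w)
        x_pad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._x_pad = x_pad if train else None
        y = np.empty((b, oh, ow, self.weight.shape[0]), dtype=np.float32)
        y[:] = self.bias
        for di in range(k):
            for dj in range(k):
                xs = x_pad[:, :, di : di + s * oh : s, dj : dj + s * ow : s]
                # (B,C,OH,OW) x (O,C) -> (B,OH,OW,O)
                y += np.tensordot(xs, self.weight[:, :, di, dj], axes=([1], [1]))
        return np.ascontiguousarray(np.moveaxis(y, 3, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x_pad is not None, "forward(train=True) must precede backward"
        x_pad = self._x_pad
        k, s, p = self.ksize, self.stride, self.pad
        b, _, oh, ow = dy.shape
        self.dbias[:] = dy.sum(axis=(0, 2, 3))
        dx_pad = np.zeros_like(x_pad)
        for di in range(k):
            for dj in range(k):
                xs = x_pad[:, :, di : di + s * oh : s, dj : dj + s * ow : s]
                # dW[o,c] = sum_{b,i,j} dy[b,o,i,j] * xs[b,c,i,j]
                self.dweight[:, :, di, dj] = np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                # dx[b,c,i,j] += sum_o dy[b,o,i,j] * W[o,c]
                dxs = np.tensordot(dy, self.weight[:, :, di, dj], axes=([1], [0]))
                dx_pad[:, :, di : di + s * oh : s, dj : dj + s * ow : s] += np.moveaxis(
                    dxs, 3, 1
                )
        self._x_pad = None
        if p:
            return dx_pad[:, :, p:-p, p:-p]
        return dx_pad

    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    def grads(self) -> list[np.ndarray]:
        return [self.dweight, self.dbias]

    def buffers(self) -> list[np.ndarray]:
        return []


class BatchNorm2d:
    """Per-channel batch normalization over (B, H, W).

    Training mode normalizes by batch statistics and updates running
    estimates (momentum 0.1); eval mode uses the running estimates.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (x_hat, inv_std)
        return (self.gamma[None, :, None, None] * x_hat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x_hat, inv_std = self._cache
        self._cache = None
        self.dgamma[:] = (dy * x_hat).sum(axis=(0, 2, 3))
        self.dbeta[:] = dy.sum(axis=(0, 2, 3))
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        g = (self.gamma * inv_std)[None, :, None, None]
        mean_dy = dy.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dy_xhat = (dy * x_hat).mean(axis=(0, 2, 3))[None, :, None, None]
        return (g * (dy - mean_dy - x_hat * mean_dy_xhat)).astype(np.float32)

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def grads(self) -> list[np.ndarray]:
        return [self.dgamma, self.dbeta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []


class Sequential:
    def __init__(self, *layers) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in layer.buffers()]


class Adam:
    """Adam with bias correction and decoupled weight decay (AdamW style).

    ``decay_mask`` flags which parameter arrays receive weight decay
    (convolution weights yes, biases no); decay is applied directly to the
    parameter, not through the moment estimates.
    """

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_mask: list[bool] | None = None,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask or [p.ndim > 1 for p in params]
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v, decay in zip(self.params, grads, self.m, self.v, self.decay_mask):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if decay and self.weight_decay:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
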