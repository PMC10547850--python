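"""Minimal 3D convolutional network machinery in NumPy.

A small encoder-decoder (U-Net topology: strided-resolution levels with
skip connections) for image-to-image regression, with hand-written forward
and backward passes.  Convolutions are evaluated as im2col + GEMM, which
keeps the arithmetic in BLAS; gradients with respect to inputs reuse the
same machinery with the spatially flipped, transposed kernel.  Everything
is float32 and driven by an explicit Generator, so training is bit
reproducible for a fixed seed on a fixed BLAS.

Tensors are (channels, X, Y, Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet3D", "Adam", "mse_loss"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, X, Y, Z) -> (X*Y*Z, C*27) patches of the zero-padded input."""
    c = x.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C, X, Y, Z, 3,3,3)
    win = win.transpose(1, 2, 3, 0, 4, 5, 6)
    return np.ascontiguousarray(win).reshape(-1, c * 27)


class _Conv3x3:
    """Same-padding 3x3x3 convolution with bias."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 27))
        self.w = (rng.standard_normal((cout, cin, 3, 3, 3)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = _im2col(x)
        if train:
            self._cols, self._shape = cols, x.shape
        y = cols @ self.w.reshape(len(self.w), -1).T + self.b
        return y.T.reshape((len(self.w),) + x.shape[1:])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cout = len(self.w)
        dyf = dy.reshape(cout, -1).T  # (N, cout)
        self.dw += (dyf.T @ self._cols).reshape(self.w.shape)
        self.db += dyf.sum(axis=0)
        # dx = conv(dy, flipped-transposed kernel)
        wf = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)  # (cin, cout,3,3,3)
        cols_dy = _im2col(dy)
        dx = cols_dy @ wf.reshape(len(wf), -1).T
        return dx.T.reshape(self._shape)


class _Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cout, cin)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return np.tensordot(self.w, x, axes=1) + self.b[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw += np.tensordot(dy.reshape(len(dy), -1), self._x.reshape(len(self._x), -1).T, axes=1)
        self.db += dy.sum(axis=(1, 2, 3))
        return np.tensordot(self.w.T, dy, axes=1)


def _leaky(x: np.ndarray, slope: float = 0.1) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float = 0.1) -> np.ndarray:
    return np.where(x > 0, 1.0, slope).astype(np.float32)


def _pool2(x: np.ndarray) -> np.ndarray:
    c, a, b, d = x.shape
    return x.reshape(c, a // 2, 2, b // 2, 2, d // 2, 2).mean(axis=(2, 4, 6))


def _pool2_grad(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(dy, 2, 1), 2, 2), 2, 3) / 8.0


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(x, 2, 1), 2, 2), 2, 3)


def _up2_grad(dy: np.ndarray) -> np.ndarray:
    c, a, b, d = dy.shape
    return dy.reshape(c, a // 2, 2, b // 2, 2, d // 2, 2).sum(axis=(2, 4, 6))


@dataclass
class _Block:
    """One conv + LeakyReLU, with cached pre-activation for backward."""

    conv: _Conv3x3
    _pre: np.ndarray | None = field(default=None, repr=False)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = self.conv.forward(x, train)
        if train:
            self._pre = z
        return _leaky(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(dy * _leaky_grad(self._pre))


class UNet3D:
    """Two-down/two-up U-Net for volumetric regression.

    ``base`` channels at full resolution, doubling per level; nearest
    upsampling, skip concatenation, dropout on the bottleneck during
    training.  Spatial dims must be divisible by 4.
    """

    def __init__(
        self,
        in_channels: int = 3,
        out_channels: int = 1,
        base: int = 8,
        dropout: float = 0.1,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        b = base
        self.dropout = float(dropout)
        self.enc0 = _Block(_Conv3x3(in_channels, b, rng))
        self.enc1 = _Block(_Conv3x3(b, 2 * b, rng))
        self.bott = _Block(_Conv3x3(2 * b, 4 * b, rng))
        self.dec1 = _Block(_Conv3x3(4 * b + 2 * b, 2 * b, rng))
        self.dec0 = _Block(_Conv3x3(2 * b + b, b, rng))
        self.head = _Conv1x1(b, out_channels, rng)
        # zero-initialised head: the untrained network predicts exactly 0
        # (no volume change), the natural prior for a residual quantity
        self.head.w[...] = 0.0
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------
    def _convs(self):
        return [self.enc0.conv, self.enc1.conv, self.bott.conv,
                self.dec1.conv, self.dec0.conv, self.head]

    def parameters(self) -> list[np.ndarray]:
        out = []
        for c in self._convs():
            out.extend([c.w, c.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for c in self._convs():
            out.extend([c.dw, c.db])
        return out

    def zero_grad(self) -> None:
        for c in self._convs():
            c.dw[...] = 0
            c.db[...] = 0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        e0 = self.enc0.forward(x, train)
        p0 = _pool2(e0)
        e1 = self.enc1.forward(p0, train)
        p1 = _pool2(e1)
        bt = self.bott.forward(p1, train)
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = (rng.random(bt.shape) >= self.dropout).astype(np.float32)
            keep /= 1.0 - self.dropout
            bt = bt * keep
            self._cache["drop"] = keep
        u1 = _up2(bt)
        c1 = np.concatenate([u1, e1], axis=0)
        d1 = self.dec1.forward(c1, train)
        u0 = _up2(d1)
        c0 = np.concatenate([u0, e0], axis=0)
        d0 = self.dec0.forward(c0, train)
        y = self.head.forward(d0, train)
        if train:
            self._cache["splits"] = (u1.shape[0], u0.shape[0])
        return y

    def backward(self, dy: np.ndarray) -> None:
        n_u1, n_u0 = self._cache["splits"]
        dd0 = self.head.backward(np.ascontiguousarray(dy, dtype=np.float32))
        dc0 = self.dec0.backward(dd0)
        du0, de0_skip = dc0[:n_u0], dc0[n_u0:]
        dd1 = _up2_grad(du0)
        dc1 = self.dec1.backward(dd1)
        du1, de1_skip = dc1[:n_u1], dc1[n_u1:]
        dbt = _up2_grad(du1)
        if self.dropout > 0:
            dbt = dbt * self._cache["drop"]
        dp1 = self.bott.backward(dbt)
        de1 = _pool2_grad(dp1) + de1_skip
        dp0 = self.enc1.backward(de1)
        de0 = _pool2_grad(dp0) + de0_skip
        self.enc0.backward(de0)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = (pred - target).astype(np.float32)
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer over a fixed parameter list (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
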