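"""Layers, tensor rearrangements and the Adam optimizer."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def space_to_depth(x: np.ndarray, k: int) -> np.ndarray:
    """Rearrange (C, D, H, W) -> (C*k^3, D/k, H/k, W/k).

    The "holistic decomposition" input stage: a bijective, parameter-free
    rearrangement that trades spatial resolution for channels so that the
    network body sees the full field of view at reduced grid size.
    3D inputs are treated as single-channel and returned with an explicit
    channel axis.
    """
    if k < 1 or int(k) != k:
        raise ValueError("k must be a positive integer")
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected (C, D, H, W) or (D, H, W)")
    c, d, h, w = x.shape
    if d % k or h % k or w % k:
        raise ValueError(f"spatial dims {(d, h, w)} not divisible by k={k}")
    if k == 1:
        return x
    x = x.reshape(c, d // k, k, h // k, k, w // k, k)
    return np.ascontiguousarray(x.transpose(0, 2, 4, 6, 1, 3, 5)).reshape(
        c * k**3, d // k, h // k, w // k
    )


def depth_to_space(x: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`space_to_depth` (the "dense upsampling" stage)."""
    if k < 1 or int(k) != k:
        raise ValueError("k must be a positive integer")
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected (C, D, H, W) or (D, H, W)")
    c, d, h, w = x.shape
    if c % k**3:
        raise ValueError(f"channels {c} not divisible by k^3={k**3}")
    if k == 1:
        return x
    x = x.reshape(c // k**3, k, k, k, d, h, w)
    return np.ascontiguousarray(x.transpose(0, 4, 1, 5, 2, 6, 3)).reshape(
        c // k**3, d * k, h * k, w * k
    )


class Layer:
    """A layer with cached forward state and in-place accumulated grads."""

    params: list

    def __init__(self):
        self.params = []

    def zero_grad(self):
        for p in self.params:
            p["grad"][...] = 0.0


class Conv3d(Layer):
    """Stride-1 zero-padded ("same") 3D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, ksize: int = 3):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        fan_in = c_in * ksize**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
        c = x.shape[0]
        return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
            -1, c * k**3
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.shape_in = x.shape
        self.cols = self._im2col(x)
        y = self.cols @ self.W.T + self.b
        d, h, w = x.shape[1:]
        return np.ascontiguousarray(y.T).reshape(self.c_out, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d, h, w = self.shape_in[1:]
        dyf = np.ascontiguousarray(dy.reshape(self.c_out, -1).T)
        self.dW += dyf.T @ self.cols
        self.db += dyf.sum(axis=0)
        # grad wrt input = "same" conv of dy with spatially-flipped kernels,
        # in/out channels swapped (exact for stride 1, zero padding)
        k = self.k
        wf = (
            self.W.reshape(self.c_out, self.c_in, k, k, k)[:, :, ::-1, ::-1, ::-1]
            .transpose(1, 0, 2, 3, 4)
            .reshape(self.c_in, self.c_out * k**3)
        )
        saved_cin, self.c_in = self.c_in, self.c_out  # reuse _im2col on dy
        cols_dy = self._im2col(dy)
        self.c_in = saved_cin
        dx = cols_dy @ wf.T
        self.cols = None
        return np.ascontiguousarray(dx.T).reshape(self.c_in, d, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return np.where(self.mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self.mask, dy, 0.0)


class AvgPool3d(Layer):
    """2x2x2 average pooling."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.f = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.f
        c, d, h, w = x.shape
        if d % f or h % f or w % f:
            raise ValueError(f"spatial dims {(d, h, w)} not divisible by {f}")
        self.shape_in = x.shape
        return x.reshape(c, d // f, f, h // f, f, w // f, f).mean(axis=(2, 4, 6))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.f
        dy = dy / f**3
        for ax in (1, 2, 3):
            dy = np.repeat(dy, f, axis=ax)
        return dy


class Upsample3d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.f = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        for ax in (1, 2, 3):
            x = np.repeat(x, self.f, axis=ax)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.f
        c, d, h, w = dy.shape
        return dy.reshape(c, d // f, f, h // f, f, w // f, f).sum(axis=(2, 4, 6))


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for layer in layers for p in layer.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in self.params]
        self.v = [np.zeros_like(p["value"]) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p["grad"][...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p["value"] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
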