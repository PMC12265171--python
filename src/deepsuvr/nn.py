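"""Minimal NumPy neural-network layers with analytic backpropagation.

Only what the correction-factor network needs: non-overlapping stride-4
3D convolution (exact patch matmul), instance/batch normalisation,
leaky rectification, tanh, dropout, affine layers, a doubled logistic
head, and Adam.  Layers cache their forward activations and expose a
``backward`` that returns the gradient w.r.t. their input.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5

#: Computation dtype for network weights and activations.
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3dStride4(Layer):
    """3D convolution with kernel 4 and stride 4 (non-overlapping patches).

    Input (N, C, X, Y, Z); trailing voxels beyond a multiple of 4 on any
    axis are cropped.  Equivalent to a matmul over 4x4x4 patches.
    """

    K = 4

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * self.K**3
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Param(rng.uniform(-bound, bound, size=(fan_in, c_out)))
        self.bias = Param(rng.uniform(-bound, bound, size=(c_out,)))
        self.c_in, self.c_out = c_in, c_out
        #: the first layer of a network sets this: its input is data, so
        #: no input gradient is needed (saves the dominant transpose)
        self.skip_input_grad = False

    def params(self):
        return [self.weight, self.bias]

    @classmethod
    def out_shape(cls, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(s // cls.K for s in spatial)

    def forward(self, x, train):
        k = self.K
        n, c = x.shape[:2]
        self._full_spatial = x.shape[2:]
        xo, yo, zo = (s // k for s in x.shape[2:])
        x = x[:, :, : xo * k, : yo * k, : zo * k]
        patches = (
            x.reshape(n, c, xo, k, yo, k, zo, k)
            .transpose(0, 2, 4, 6, 1, 3, 5, 7)
            .reshape(n, xo * yo * zo, c * k**3)
        )
        self._patches = patches
        self._in_shape = (n, c, xo, yo, zo)
        out = patches @ self.weight.value + self.bias.value
        return out.transpose(0, 2, 1).reshape(n, self.c_out, xo, yo, zo)

    def backward(self, grad):
        n, c, xo, yo, zo = self._in_shape
        k = self.K
        g = grad.reshape(n, self.c_out, -1).transpose(0, 2, 1)  # (N, P, Cout)
        f = self._patches.shape[-1]
        self.weight.grad += self._patches.reshape(-1, f).T @ g.reshape(-1, self.c_out)
        self.bias.grad += g.sum(axis=(0, 1))
        if self.skip_input_grad:
            return None
        gp = g @ self.weight.value.T  # (N, P, C*k^3)
        gx = (
            gp.reshape(n, xo, yo, zo, c, k, k, k)
            .transpose(0, 4, 1, 5, 2, 6, 3, 7)
            .reshape(n, c, xo * k, yo * k, zo * k)
        )
        if gx.shape[2:] != self._full_spatial:  # cropped voxels get zero gradient
            full = np.zeros((n, c) + self._full_spatial)
            full[:, :, : xo * k, : yo * k, : zo * k] = gx
            gx = full
        return gx


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalisation over spatial voxels (no affine)."""

    def forward(self, x, train):
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._std = np.sqrt(var + _EPS)
        self._xhat = (x - mu) / self._std
        return self._xhat

    def backward(self, grad):
        axes = (2, 3, 4)
        xhat = self._xhat
        gm = grad.mean(axis=axes, keepdims=True)
        gxm = (grad * xhat).mean(axis=axes, keepdims=True)
        return (grad - gm - xhat * gxm) / self._std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Param(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Param(rng.uniform(-bound, bound, size=(d_out,)))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class BatchNorm1d(Layer):
    def __init__(self, dim: int, momentum: float = 0.1):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._std = np.sqrt(var + _EPS)
            self._xhat = (x - mu) / self._std
            self._train = True
        else:
            self._std = np.sqrt(self.running_var + _EPS)
            self._xhat = (x - self.running_mean) / self._std
            self._train = False
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not self._train:
            return g / self._std
        return (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) / self._std


class Tanh(Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.rate
        self._mask = keep.astype(x.dtype) / x.dtype.type(1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class DoubledSigmoid(Layer):
    """y = 2 * logistic(x): squashes the head into [0, 2]."""

    def forward(self, x, train):
        self._y = 2.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        s = self._y / 2.0
        return grad * 2.0 * s * (1.0 - s)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
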