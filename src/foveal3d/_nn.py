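"""Minimal numpy building blocks for 3D fully convolutional networks.

Implements exactly the layer set the foveal architecture needs -- valid 3D
convolution, per-channel batch normalization, ReLU, nearest-neighbor
upsampling, channel concatenation and softmax -- each with an explicit
backward pass, plus the AdaDelta optimizer.

All tensors are float32 in channels-last layout ``(N, X, Y, Z, C)``; the
convolution is computed as an accumulation of one GEMM per kernel offset
over contiguous crops, which keeps the heavy lifting in BLAS without the
cost of materializing a full im2col buffer.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Conv3d:
    """Valid (unpadded) 3D convolution; each k^3 kernel removes k-1 voxels
    per axis. Weight layout ``(k, k, k, C_in, C_out)``."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv"):
        k = int(kernel)
        fan_in = in_ch * k ** 3
        # He initialization, appropriate for the ReLU blocks downstream
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(k, k, k, in_ch, out_ch))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), f"{name}.bias")
        self.kernel = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cache = None

    @property
    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.kernel
        n = x.shape[0]
        do, ho, wo = (s - k + 1 for s in x.shape[1:4])
        w = self.weight.value
        out = np.empty((n * do * ho * wo, self.out_ch), dtype=np.float32)
        out[:] = self.bias.value
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(
                        x[:, i:i + do, j:j + ho, l:l + wo, :]
                    ).reshape(-1, self.in_ch)
                    out += xs @ w[i, j, l]
        if train:
            self._cache = x
        return out.reshape(n, do, ho, wo, self.out_ch)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._cache
        k = self.kernel
        n, do, ho, wo, _ = g.shape
        gmat = np.ascontiguousarray(g).reshape(-1, self.out_ch)
        self.bias.grad += gmat.sum(axis=0)
        dx = np.zeros_like(x)
        dw = self.weight.grad
        wv = self.weight.value
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    sl = (slice(None), slice(i, i + do), slice(j, j + ho),
                          slice(l, l + wo), slice(None))
                    xs = np.ascontiguousarray(x[sl]).reshape(-1, self.in_ch)
                    dw[i, j, l] += xs.T @ gmat
                    dx[sl] += (gmat @ wv[i, j, l].T).reshape(
                        n, do, ho, wo, self.in_ch)
        self._cache = None
        return dx


class BatchNorm3d:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
            ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat = (x - mean.astype(np.float32)) * ivar
            self._cache = (xhat, ivar)
        else:
            ivar = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * ivar.astype(np.float32)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        axes = (0, 1, 2, 3)
        nv = g.size // g.shape[-1]
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        dxhat = g * self.gamma.value
        dx = (ivar / nv) * (
            nv * dxhat
            - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class UpsampleNearest:
    """Integer-factor nearest-neighbor upsampling of the spatial axes."""

    params: list = []

    def __init__(self, factor: int = 2):
        self.factor = int(factor)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        f = self.factor
        return x.repeat(f, axis=1).repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        f = self.factor
        n, x, y, z, c = g.shape
        return g.reshape(n, x // f, f, y // f, f, z // f, f, c)\
                .sum(axis=(2, 4, 6))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of the channel softmax."""
    dot = (dprobs * probs).sum(axis=-1, keepdims=True)
    return (probs * (dprobs - dot)).astype(np.float32)


class AdaDelta:
    """Zeiler's AdaDelta: parameter-wise adaptive steps, no learning-rate
    schedule (lr kept as a plain multiplier, default 1)."""

    def __init__(self, params: list[Param], rho: float = 0.95,
                 eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho = rho
        self.eps = eps
        self.lr = lr
        self._eg = [np.zeros_like(p.value) for p in params]
        self._ed = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self._eg, self._ed):
            g = p.grad
            eg *= self.rho
            eg += (1.0 - self.rho) * g * g
            delta = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1.0 - self.rho) * delta * delta
            p.value += self.lr * delta

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
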