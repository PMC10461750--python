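"""Numpy layers with analytic backprop.

All tensors are float32 arrays shaped (N, C, H, W). Each layer caches what its
backward pass needs; backward(grad) returns the gradient w.r.t. the input and
accumulates parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2", "BilinearUp2", "Sequential"]

F32 = np.float32


class Layer:
    """Base: parameterless layers leave params/grads empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0

    def train(self, mode: bool = True):
        self.training = mode


def conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Stride-1 same-padding 3x3 convolution as nine shifted matmuls.

    Returns (out, xp) where xp is the zero-padded input (needed by the
    parameter-gradient pass).
    """
    n, c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, o, h * wd), dtype=F32)
    for u in range(3):
        for v in range(3):
            xv = np.ascontiguousarray(xp[:, :, u : u + h, v : v + wd]).reshape(n, c, h * wd)
            out += w[:, :, u, v] @ xv
    return out.reshape(n, o, h, wd) + b[None, :, None, None], xp


def conv3_input_grad(grad: np.ndarray, w: np.ndarray) -> np.ndarray:
    """dL/dx for conv3_forward: full correlation with flipped kernels."""
    n, o, h, wd = grad.shape
    c = w.shape[1]
    gp = np.pad(grad, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dx = np.zeros((n, c, h * wd), dtype=F32)
    for u in range(3):
        for v in range(3):
            gv = np.ascontiguousarray(
                gp[:, :, 2 - u : 2 - u + h, 2 - v : 2 - v + wd]
            ).reshape(n, o, h * wd)
            dx += w[:, :, u, v].T @ gv
    return dx.reshape(n, c, h, wd)


def conv3_param_grad(xp: np.ndarray, grad: np.ndarray, dw_out: np.ndarray, db_out: np.ndarray):
    """Accumulate dL/dW and dL/db given the padded input and output grad."""
    n, o, h, wd = grad.shape
    c = xp.shape[1]
    gf = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(o, -1)
    for u in range(3):
        for v in range(3):
            xv = np.ascontiguousarray(
                xp[:, :, u : u + h, v : v + wd].transpose(1, 0, 2, 3)
            ).reshape(c, -1)
            dw_out[:, :, u, v] += gf @ xv.T
    db_out += grad.sum(axis=(0, 2, 3))


class Conv2d(Layer):
    """3x3 stride-1 same-padding convolution (He-initialized)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if k != 3:
            raise ValueError("only 3x3 kernels are supported")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.params = {
            "W": rng.normal(0.0, scale, (c_out, c_in, k, k)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._xp = None

    def forward(self, x):
        out, xp = conv3_forward(x.astype(F32), self.params["W"], self.params["b"])
        if self.training:
            self._xp = xp
        return out

    def backward(self, grad):
        grad = grad.astype(F32)
        conv3_param_grad(self._xp, grad, self.grads["W"], self.grads["b"])
        self._xp = None
        return conv3_input_grad(grad, self.params["W"])


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=F32), "beta": np.zeros(c, dtype=F32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g_sum = grad.sum(axis=(0, 2, 3))
        gx_sum = (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["gamma"] += gx_sum
        self.grads["beta"] += g_sum
        gamma_inv = (self.params["gamma"] * inv)[None, :, None, None]
        dx = gamma_inv * (
            grad - (g_sum[None, :, None, None] + xhat * gx_sum[None, :, None, None]) / n
        )
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Requires even H and W."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(out, self._arg[..., None], grad[..., None].astype(F32), axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._arg = None
        return np.ascontiguousarray(out).reshape(n, c, h, w)


def _up2_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) factor-2 bilinear interpolation (align_corners=False)."""
    m = np.zeros((2 * n, n), dtype=F32)
    for o in range(2 * n):
        src = (o + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        m[o, lo_c] += 1.0 - frac
        m[o, hi_c] += frac
    return m


class BilinearUp2(Layer):
    """Factor-2 bilinear upsampling; backward is the exact transpose."""

    _cache_m: dict[int, np.ndarray] = {}

    def _m(self, n):
        if n not in self._cache_m:
            self._cache_m[n] = _up2_matrix(n)
        return self._cache_m[n]

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        mr, mc = self._m(h), self._m(w)
        return (mr @ x @ mc.T).astype(F32)

    def backward(self, grad):
        _, _, h, w = self._shape
        mr, mc = self._m(h), self._m(w)
        return (mr.T @ grad @ mc).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for layer in self.layers:
            layer.train(mode)

    def named_params(self, prefix=""):
        out = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out += layer.named_params(f"{prefix}{i}.")
            else:
                for k in layer.params:
                    out.append((f"{prefix}{i}.{k}", layer, k))
        return out
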