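"""Layer objects for the numpy network engine.

Each layer owns a ``params`` dict of numpy arrays and a parallel
``grads`` dict filled by ``backward``.  ``forward`` caches whatever the
backward pass needs; backward must therefore follow the most recent
forward.  ``output_shape`` does pure shape arithmetic (no data) so
architectures can be validated and summarised before any computation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .. import enk_core
from ..errors import DimensionError
from . import functional as F


class Layer:
    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - default
        pass

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 padding: str = "valid", bias: bool = True, name: str = "conv"):
        super().__init__(name)
        self.in_ch, self.out_ch, self.kernel, self.padding = in_ch, out_ch, kernel, padding
        self.bias = bias
        kh, kw = kernel
        self.params["W"] = np.zeros((out_ch, in_ch, kh, kw))
        if bias:
            self.params["b"] = np.zeros(out_ch)
        self.zero_grad()

    def init(self, rng: np.random.Generator) -> None:
        kh, kw = self.kernel
        fan_in, fan_out = self.in_ch * kh * kw, self.out_ch * kh * kw
        self.params["W"] = _glorot(rng, self.params["W"].shape, fan_in, fan_out)

    def forward(self, x, training=False, rng=None):
        y, self._cache = F.conv2d_forward(
            x, self.params["W"], self.params.get("b"), self.padding)
        return y

    def backward(self, gy):
        gx, gW, gb = F.conv2d_backward(gy, self._cache)
        self.grads["W"] += gW
        if gb is not None:
            self.grads["b"] += gb
        return gx

    def output_shape(self, shape):
        B, C, H, W = shape
        kh, kw = self.kernel
        (pt, pb), (pl, pr) = F.pad_for(kh, kw, self.padding)
        Ho, Wo = H + pt + pb - kh + 1, W + pl + pr - kw + 1
        if Ho < 1 or Wo < 1:
            raise DimensionError(
                f"{self.name}: plane {H}x{W} too small for {kh}x{kw} kernel")
        return (B, self.out_ch, Ho, Wo)


class DepthwiseConv2d(Layer):
    def __init__(self, in_ch: int, depth_mult: int, kernel: tuple[int, int],
                 padding: str = "valid", name: str = "depthwise"):
        super().__init__(name)
        self.in_ch, self.depth_mult, self.kernel, self.padding = in_ch, depth_mult, kernel, padding
        kh, kw = kernel
        self.params["W"] = np.zeros((in_ch, depth_mult, kh, kw))
        self.zero_grad()

    def init(self, rng):
        kh, kw = self.kernel
        self.params["W"] = _glorot(rng, self.params["W"].shape, kh * kw,
                                   self.depth_mult * kh * kw)

    def forward(self, x, training=False, rng=None):
        y, self._cache = F.depthwise_conv2d_forward(x, self.params["W"], self.padding)
        return y

    def backward(self, gy):
        gx, gW = F.depthwise_conv2d_backward(gy, self._cache)
        self.grads["W"] += gW
        return gx

    def output_shape(self, shape):
        B, C, H, W = shape
        kh, kw = self.kernel
        (pt, pb), (pl, pr) = F.pad_for(kh, kw, self.padding)
        Ho, Wo = H + pt + pb - kh + 1, W + pl + pr - kw + 1
        if Ho < 1 or Wo < 1:
            raise DimensionError(
                f"{self.name}: plane {H}x{W} too small for {kh}x{kw} kernel")
        return (B, C * self.depth_mult, Ho, Wo)


class BatchNorm2d(Layer):
    """Per-map batch normalisation with running statistics for inference."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-3,
                 name: str = "batchnorm"):
        super().__init__(name)
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch)
        self.params["beta"] = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.zero_grad()

    def forward(self, x, training=False, rng=None):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, training, x.shape)
        return g * xhat + b

    def backward(self, gy):
        xhat, invstd, training, shape = self._cache
        axes = (0, 2, 3)
        self.grads["gamma"] += (gy * xhat).sum(axis=axes)
        self.grads["beta"] += gy.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        gxhat = gy * g
        if not training:
            return gxhat * invstd[None, :, None, None]
        N = shape[0] * shape[2] * shape[3]
        s1 = gxhat.sum(axis=axes, keepdims=True)
        s2 = (gxhat * xhat).sum(axis=axes, keepdims=True)
        return (invstd[None, :, None, None] / N) * (N * gxhat - s1 - xhat * s2)

    def output_shape(self, shape):
        return shape


class Activation(Layer):
    def __init__(self, kind: str, name: Optional[str] = None):
        super().__init__(name or kind)
        if kind not in ("elu", "relu", "square", "safelog"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training=False, rng=None):
        if self.kind == "elu":
            y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        elif self.kind == "relu":
            y = np.maximum(x, 0.0)
        elif self.kind == "square":
            y = x * x
        else:  # safelog, clamped below as in ShallowConvNet-style pipelines
            y = np.log(np.maximum(x, 1e-6))
        self._cache = (x, y)
        return y

    def backward(self, gy):
        x, y = self._cache
        if self.kind == "elu":
            return gy * np.where(x > 0, 1.0, y + 1.0)
        if self.kind == "relu":
            return gy * (x > 0)
        if self.kind == "square":
            return gy * 2.0 * x
        return gy * np.where(x > 1e-6, 1.0 / np.maximum(x, 1e-6), 0.0)

    def output_shape(self, shape):
        return shape


class AvgPool2d(Layer):
    def __init__(self, pool: tuple[int, int], stride: Optional[tuple[int, int]] = None,
                 name: str = "avgpool"):
        super().__init__(name)
        self.pool = pool
        self.stride = stride or pool

    def forward(self, x, training=False, rng=None):
        y, self._cache = F.avg_pool2d_forward(x, self.pool, self.stride)
        return y

    def backward(self, gy):
        return F.avg_pool2d_backward(gy, self._cache)

    def output_shape(self, shape):
        B, C, H, W = shape
        ph, pw = self.pool
        sh, sw = self.stride
        if H < ph or W < pw:
            raise DimensionError(f"{self.name}: plane {H}x{W} too small for {ph}x{pw} pool")
        return (B, C, (H - ph) // sh + 1, (W - pw) // sw + 1)


class MaxPool2d(AvgPool2d):
    def __init__(self, pool, stride=None, name="maxpool"):
        super().__init__(pool, stride, name)

    def forward(self, x, training=False, rng=None):
        y, self._cache = F.max_pool2d_forward(x, self.pool, self.stride)
        return y

    def backward(self, gy):
        return F.max_pool2d_backward(gy, self._cache)


class Dropout(Layer):
    def __init__(self, p: float, name: str = "dropout"):
        super().__init__(name)
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG for its mask")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask

    def output_shape(self, shape):
        return shape


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__(name)

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)

    def output_shape(self, shape):
        return (shape[0], int(np.prod(shape[1:])))


class GlobalAvgPool(Layer):
    def __init__(self, name: str = "gap"):
        super().__init__(name)

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        B, C, H, W = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape) / (H * W)

    def output_shape(self, shape):
        return (shape[0], shape[1])


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, name: str = "dense"):
        super().__init__(name)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["W"] = np.zeros((in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim)
        self.zero_grad()

    def init(self, rng):
        self.params["W"] = _glorot(rng, (self.in_dim, self.out_dim),
                                   self.in_dim, self.out_dim)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads["W"] += self._x.T @ gy
        self.grads["b"] += gy.sum(axis=0)
        return gy @ self.params["W"].T

    def output_shape(self, shape):
        if shape[1] != self.in_dim:
            raise DimensionError(
                f"{self.name}: expected {self.in_dim} inputs, got {shape[1]}")
        return (shape[0], self.out_dim)


class EnKLayer(Layer):
    """Time-encoding layer: shape-preserving additive decomposition.

    Wraps :func:`enkit.enk_core.enk_forward` / :func:`enk_vjp` so the
    decomposition's per-time-step affine weights and artifact kernel are
    trained jointly with the host network.  Initialised near
    pass-through (w=1, b=0, averaging kernel).
    """

    def __init__(self, n: int, k: int, l: int = 1, m: int = 7,
                 shared_affine: bool = True, name: str = "enk"):
        super().__init__(name)
        self.n, self.k, self.l, self.m = n, k, l, m
        self.shared_affine = shared_affine
        p = enk_core.init_params(n, k, l, m, shared_affine=shared_affine)
        self.params["w"] = p.w
        self.params["b"] = p.b
        self.params["K"] = p.K
        if not shared_affine:
            self.params["w_s"] = p.w_s
            self.params["b_s"] = p.b_s
        self.zero_grad()

    def _enk_params(self) -> enk_core.EnKParams:
        return enk_core.EnKParams(
            w=self.params["w"], b=self.params["b"], K=self.params["K"],
            shared_affine=self.shared_affine,
            w_s=self.params.get("w_s"), b_s=self.params.get("b_s"))

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._decomp = enk_core.enk_forward(x, self._enk_params())
        return self._decomp.Y

    def backward(self, gy):
        g = enk_core.enk_vjp(self._x, self._enk_params(), self._decomp, gy)
        for key in self.params:
            self.grads[key] += g[key]
        return g["X"]

    def output_shape(self, shape):
        if shape[-1] != self.k:
            raise DimensionError(
                f"{self.name}: sized for k={self.k} samples, input has {shape[-1]}")
        return shape


class RCL(Layer):
    """Recurrent convolution layer: a feed-forward map plus a shared
    recurrent convolution iterated a fixed number of times.

    ``h_0 = relu(ff)``, ``h_i = relu(ff + W_r * h_{i-1})`` with the same
    recurrent kernel at every iteration, letting one layer integrate an
    increasingly wide temporal context.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int] = (1, 3),
                 iters: int = 3, name: str = "rcl"):
        super().__init__(name)
        self.in_ch, self.out_ch, self.kernel, self.iters = in_ch, out_ch, kernel, iters
        kh, kw = kernel
        self.params["Wf"] = np.zeros((out_ch, in_ch, kh, kw))
        self.params["bf"] = np.zeros(out_ch)
        self.params["Wr"] = np.zeros((out_ch, out_ch, kh, kw))
        self.zero_grad()

    def init(self, rng):
        kh, kw = self.kernel
        self.params["Wf"] = _glorot(rng, self.params["Wf"].shape,
                                    self.in_ch * kh * kw, self.out_ch * kh * kw)
        # small recurrent weights keep the unrolled map contractive at start
        self.params["Wr"] = 0.1 * _glorot(rng, self.params["Wr"].shape,
                                          self.out_ch * kh * kw, self.out_ch * kh * kw)

    def forward(self, x, training=False, rng=None):
        ff, ff_cache = F.conv2d_forward(x, self.params["Wf"], self.params["bf"], "same")
        h = np.maximum(ff, 0.0)
        steps = [(None, ff > 0, None)]  # (rec cache, relu mask, h_prev)
        for _ in range(self.iters):
            r, r_cache = F.conv2d_forward(h, self.params["Wr"], None, "same")
            z = ff + r
            h_new = np.maximum(z, 0.0)
            steps.append((r_cache, z > 0, h))
            h = h_new
        self._cache = (ff_cache, steps)
        return h

    def backward(self, gy):
        ff_cache, steps = self._cache
        g_ff = np.zeros_like(gy)
        gh = gy
        for r_cache, mask, _h_prev in reversed(steps[1:]):
            gz = gh * mask
            g_ff += gz
            gh, gWr, _ = F.conv2d_backward(gz, r_cache)
            self.grads["Wr"] += gWr
        g_ff += gh * steps[0][1]  # h_0 = relu(ff)
        gx, gWf, gbf = F.conv2d_backward(g_ff, ff_cache)
        self.grads["Wf"] += gWf
        self.grads["bf"] += gbf
        return gx

    def output_shape(self, shape):
        return (shape[0], self.out_ch, shape[2], shape[3])
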