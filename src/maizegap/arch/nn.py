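"""Minimal NumPy layer framework for structural model analysis.

Supports exactly what the seedling-detector architecture needs: 2-D
convolution (strides, groups), batch/group/layer norm, SiLU, max pooling,
nearest-neighbor upsampling and dense linear maps, on single images laid
out channel-first ``(C, H, W)`` in float32. A thread-local profiler
accumulates multiply-accumulate counts of conv and linear layers during a
forward pass; FLOPs are reported as 2 x MAC, the convention of the common
detection-model profilers.

The framework is for architecture accounting and shape verification, not
training: there is no autograd.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module",
    "Param",
    "Profiler",
    "Conv2d",
    "BatchNorm2d",
    "GroupNorm",
    "LayerNorm",
    "Linear",
    "silu",
    "sigmoid",
    "softmax",
    "max_pool2d",
    "upsample_nearest2x",
]


class Profiler:
    """Accumulates conv/linear MACs during forward passes."""

    _active: "Profiler | None" = None

    def __init__(self) -> None:
        self.macs = 0

    def __enter__(self) -> "Profiler":
        Profiler._active = self
        self.macs = 0
        return self

    def __exit__(self, *exc) -> None:
        Profiler._active = None

    @classmethod
    def add(cls, macs: int) -> None:
        if cls._active is not None:
            cls._active.macs += int(macs)


class Param:
    """A weight array with a trainable flag."""

    __slots__ = ("data", "trainable")

    def __init__(self, data: np.ndarray, trainable: bool = True):
        self.data = np.asarray(data, dtype=np.float32)
        self.trainable = trainable


class Module:
    """Base class; children and params are discovered from attributes."""

    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def own_params(self):
        for value in self.__dict__.values():
            if isinstance(value, Param):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Param):
                        yield v

    def parameters(self):
        yield from self.own_params()
        for child in self.children():
            yield from child.parameters()

    def param_count(self, trainable_only: bool = True) -> int:
        return sum(
            p.data.size for p in self.parameters() if p.trainable or not trainable_only
        )

    def __call__(self, *args):
        return self.forward(*args)

    def forward(self, *args):  # pragma: no cover - abstract
        raise NotImplementedError


def silu(x: np.ndarray) -> np.ndarray:
    return x * sigmoid(x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _conv2d_raw(
    x: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray | None,
    stride: int,
    padding: int,
    groups: int,
) -> np.ndarray:
    c_in, h, w = x.shape
    c_out, c_in_g, kh, kw = weight.shape
    if c_in_g * groups != c_in:
        raise ValueError("channel/group mismatch")
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding))) if padding else x
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]  # (C, ho, wo, kh, kw)
    out = np.empty((c_out, ho, wo), dtype=np.float32)
    og = c_out // groups
    for g in range(groups):
        col = (
            windows[g * c_in_g : (g + 1) * c_in_g]
            .transpose(1, 2, 0, 3, 4)
            .reshape(ho * wo, c_in_g * kh * kw)
        )
        wg = weight[g * og : (g + 1) * og].reshape(og, -1)
        out[g * og : (g + 1) * og] = (col @ wg.T).T.reshape(og, ho, wo)
    if bias is not None:
        out += bias[:, None, None]
    Profiler.add(c_in_g * kh * kw * c_out * ho * wo)
    return out


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        if c_in % groups or c_out % groups:
            raise ValueError("groups must divide both channel counts")
        fan_in = c_in // groups * k * k
        self.weight = Param(rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in // groups, k, k)))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups

    def forward(self, x: np.ndarray) -> np.ndarray:
        return _conv2d_raw(
            x,
            self.weight.data,
            None if self.bias is None else self.bias.data,
            self.stride,
            self.padding,
            self.groups,
        )


class BatchNorm2d(Module):
    """Inference-mode batch norm; running stats are buffers, not params."""

    def __init__(self, c: int, eps: float = 1e-3):
        self.weight = Param(np.ones(c))
        self.bias = Param(np.zeros(c))
        self._mean = np.zeros(c, dtype=np.float32)
        self._var = np.ones(c, dtype=np.float32)
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        scale = self.weight.data / np.sqrt(self._var + self.eps)
        shift = self.bias.data - self._mean * scale
        return x * scale[:, None, None] + shift[:, None, None]


class GroupNorm(Module):
    def __init__(self, groups: int, c: int, eps: float = 1e-5):
        if c % groups:
            raise ValueError("groups must divide the channel count")
        self.weight = Param(np.ones(c))
        self.bias = Param(np.zeros(c))
        self.groups = groups
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        g = x.reshape(self.groups, c // self.groups * h * w)
        mean = g.mean(axis=1, keepdims=True)
        var = g.var(axis=1, keepdims=True)
        out = ((g - mean) / np.sqrt(var + self.eps)).reshape(c, h, w)
        return out * self.weight.data[:, None, None] + self.bias.data[:, None, None]


class LayerNorm(Module):
    """Normalizes the last axis (token feature dimension)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.weight = Param(np.ones(dim))
        self.bias = Param(np.zeros(dim))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        return (x - mean) / np.sqrt(var + self.eps) * self.weight.data + self.bias.data


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(rng.normal(0, np.sqrt(1.0 / f_in), (f_out, f_in)))
        self.bias = Param(np.zeros(f_out)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        Profiler.add(x.size // x.shape[-1] * self.weight.data.size)
        return out


def max_pool2d(x: np.ndarray, k: int, stride: int = 1, padding: int = 0) -> np.ndarray:
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)), constant_values=-np.inf)
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return windows[:, ::stride, ::stride].max(axis=(3, 4))


def upsample_nearest2x(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
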