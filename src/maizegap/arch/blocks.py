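"""Building blocks of the seedling-detector architecture.

Standard YOLOv8-style blocks (Conv = conv + BN + SiLU, the split/concat
C2f stage, SPPF) plus the two lightweight substitutions used by the maize
variant: the spatial/channel reconstruction convolution (SCConv: an SRU
that gates spatially redundant features through a group-norm importance
weighting, then a CRU that splits channels into a rich and a cheap branch
and fuses them with a pooled softmax), and a bi-level routing attention
block (region-level top-k routing followed by token attention over the
gathered regions).
"""

from __future__ import annotations

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GroupNorm,
    LayerNorm,
    Linear,
    Module,
    Param,
    Profiler,
    max_pool2d,
    sigmoid,
    silu,
    softmax,
)

__all__ = [
    "Conv",
    "Bottleneck",
    "SCConv",
    "SCBottleneck",
    "C2f",
    "SPPF",
    "BiFormerBlock",
    "Detect",
]


class Conv(Module):
    """Convolution + batch norm + SiLU (the YOLO 'Conv' unit)."""

    def __init__(self, c_in, c_out, k=1, stride=1, groups=1, act=True, rng=None):
        self.conv = Conv2d(c_in, c_out, k, stride=stride, groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x):
        out = self.bn(self.conv(x))
        return silu(out) if self.act else out


class Bottleneck(Module):
    """Two 3x3 Convs with an optional residual connection."""

    def __init__(self, c, shortcut=True, rng=None):
        self.cv1 = Conv(c, c, 3, rng=rng)
        self.cv2 = Conv(c, c, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x):
        out = self.cv2(self.cv1(x))
        return x + out if self.shortcut else out


class SCConv(Module):
    """Spatial + channel reconstruction convolution.

    SRU: group-norm scale weights rank channel informativeness; a sigmoid
    gate splits the feature into informative / redundant halves that are
    cross-reconstructed. CRU: the channels are split in half (alpha = 1/2),
    squeezed by ``r`` = 2, transformed by a rich group-wise 3x3 branch plus
    cheap pointwise branches, and fused with a globally pooled softmax.
    All convolutions are bias-free.
    """

    def __init__(self, c, gn_groups=16, gate_threshold=0.5, alpha=0.5, r=2, gwc_groups=2, rng=None):
        if c < 2:
            raise ValueError("SCConv needs at least 2 channels for the CRU split")
        self.gn = GroupNorm(min(gn_groups, c), c)
        self.gate_threshold = gate_threshold
        up = int(alpha * c)
        low = c - up
        self.up = up
        self.squeeze1 = Conv2d(up, up // r, 1, bias=False, rng=rng)
        self.squeeze2 = Conv2d(low, low // r, 1, bias=False, rng=rng)
        self.gwc = Conv2d(up // r, c, 3, groups=gwc_groups, bias=False, rng=rng)
        self.pwc1 = Conv2d(up // r, c, 1, bias=False, rng=rng)
        self.pwc2 = Conv2d(low // r, c - low // r, 1, bias=False, rng=rng)

    def _sru(self, x):
        gn_x = self.gn(x)
        gamma = self.gn.weight.data
        w_gamma = gamma / gamma.sum()
        gate = sigmoid(gn_x * w_gamma[:, None, None])
        info = gate >= self.gate_threshold
        x1 = np.where(info, x, 0.0)
        x2 = np.where(info, 0.0, x)
        c = x.shape[0]
        h = c // 2
        return np.concatenate([x1[:h] + x2[h:], x1[h:] + x2[:h]], axis=0)

    def _cru(self, x):
        up, low = x[: self.up], x[self.up :]
        up = self.squeeze1(up)
        low = self.squeeze2(low)
        y1 = self.gwc(up) + self.pwc1(up)
        y2 = np.concatenate([self.pwc2(low), low], axis=0)
        z = np.concatenate([y1, y2], axis=0)
        pooled = z.mean(axis=(1, 2))
        weights = softmax(pooled, axis=0)
        z = z * weights[:, None, None]
        c = z.shape[0] // 2
        return z[:c] + z[c:]

    def forward(self, x):
        return self._cru(self._sru(x))


class SCBottleneck(Module):
    """C2f gradient-flow branch with the second 3x3 conv replaced by SCConv."""

    def __init__(self, c, shortcut=True, rng=None):
        self.cv1 = Conv(c, c, 3, rng=rng)
        self.sc = SCConv(c, rng=rng)
        self.shortcut = shortcut

    def forward(self, x):
        out = self.sc(self.cv1(x))
        return x + out if self.shortcut else out


class C2f(Module):
    """Split / cascade / concat stage with n gradient-flow branches."""

    def __init__(self, c_in, c_out, n=1, shortcut=False, scconv=False, rng=None):
        self.c = c_out // 2
        self.cv1 = Conv(c_in, 2 * self.c, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, c_out, 1, rng=rng)
        block = SCBottleneck if scconv else Bottleneck
        self.blocks = [block(self.c, shortcut=shortcut, rng=rng) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        outs = [y[: self.c], y[self.c :]]
        for block in self.blocks:
            outs.append(block(outs[-1]))
        return self.cv2(np.concatenate(outs, axis=0))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three cascaded 5x5 max pools."""

    def __init__(self, c_in, c_out, k=5, rng=None):
        c = c_in // 2
        self.cv1 = Conv(c_in, c, 1, rng=rng)
        self.cv2 = Conv(4 * c, c_out, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(np.concatenate(y, axis=0))


class BiFormerBlock(Module):
    """Bi-level routing attention with a residual connection.

    The feature map is divided into ``region_grid`` x ``region_grid``
    windows. Region-level query/key descriptors (mean-pooled) produce an
    affinity matrix; each query region keeps its ``top_k`` most related
    regions, and token-to-token multi-head attention runs over the keys
    and values gathered from those regions only. Pre-norm residual layout.
    """

    def __init__(self, dim, n_heads=8, region_grid=4, top_k=4, rng=None):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        if top_k < 1 or top_k > region_grid * region_grid:
            raise ValueError("top_k must be in [1, region_grid^2]")
        self.norm = LayerNorm(dim)
        self.qkv = Linear(dim, 3 * dim, bias=False, rng=rng)
        self.proj = Linear(dim, dim, bias=True, rng=rng)
        self.dim = dim
        self.n_heads = n_heads
        self.region_grid = region_grid
        self.top_k = top_k

    def forward(self, x):
        c, h, w = x.shape
        s = self.region_grid
        if c != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {c}")
        if h % s or w % s:
            raise ValueError(f"feature map {h}x{w} not divisible by region grid {s}")
        rh, rw = h // s, w // s
        tokens = x.reshape(c, h * w).T  # (N, C)
        t = self.norm(tokens)
        qkv = self.qkv(t)
        q, k, v = np.split(qkv, 3, axis=1)

        # (region, token-in-region, C) views
        def regionize(a):
            d = a.shape[-1]
            return (
                a.reshape(s, rh, s, rw, d)
                .transpose(0, 2, 1, 3, 4)
                .reshape(s * s, rh * rw, d)
            )

        grid = np.arange(h * w).reshape(h, w)
        qr = regionize(q.reshape(h, w, c))
        kr = regionize(k.reshape(h, w, c))
        vr = regionize(v.reshape(h, w, c))
        token_ids = regionize(grid[..., None])[..., 0]

        # region-level routing
        q_region = qr.mean(axis=1)
        k_region = kr.mean(axis=1)
        affinity = q_region @ k_region.T
        routed = np.argsort(-affinity, axis=1, kind="stable")[:, : self.top_k]

        dh = c // self.n_heads
        out_tokens = np.empty_like(q)
        scale = 1.0 / np.sqrt(dh)
        for r in range(s * s):
            gather = routed[r]
            kg = kr[gather].reshape(-1, c)
            vg = vr[gather].reshape(-1, c)
            qg = qr[r]
            region_out = np.empty_like(qg)
            for head in range(self.n_heads):
                sl = slice(head * dh, (head + 1) * dh)
                attn = softmax(qg[:, sl] @ kg[:, sl].T * scale, axis=1)
                region_out[:, sl] = attn @ vg[:, sl]
            out_tokens[token_ids[r]] = region_out
        out = tokens + self.proj(out_tokens)
        return out.T.reshape(c, h, w)


class _PlainConv(Module):
    """Bare conv2d with bias (no norm/activation), for head outputs."""

    def __init__(self, c_in, c_out, k=1, rng=None):
        self.conv = Conv2d(c_in, c_out, k, bias=True, rng=rng)

    def forward(self, x):
        return self.conv(x)


class Detect(Module):
    """Decoupled anchor-free detection head over multiple strides.

    Per level: a box branch (two 3x3 Convs then a 1x1 conv to
    ``4 * reg_max`` distribution bins) and a class branch (two 3x3 Convs
    then a 1x1 conv to ``num_classes`` logits). The distribution-focal
    projection vector is registered as a non-trainable parameter. The
    forward pass returns the raw per-level maps of shape
    ``(4*reg_max + nc, H/stride, W/stride)``.
    """

    def __init__(self, channels, num_classes=1, reg_max=16, rng=None):
        ch0 = channels[0]
        c2 = max(16, ch0 // 4, 4 * reg_max)
        c3 = max(ch0, min(num_classes, 100))
        self.reg_max = reg_max
        self.num_classes = num_classes
        self.box_branches = [
            [Conv(ch, c2, 3, rng=rng), Conv(c2, c2, 3, rng=rng), _PlainConv(c2, 4 * reg_max, 1, rng=rng)]
            for ch in channels
        ]
        self.cls_branches = [
            [Conv(ch, c3, 3, rng=rng), Conv(c3, c3, 3, rng=rng), _PlainConv(c3, num_classes, 1, rng=rng)]
            for ch in channels
        ]
        self.dfl_proj = Param(np.arange(reg_max, dtype=np.float32), trainable=False)

    def children(self):
        for branch in self.box_branches + self.cls_branches:
            yield from branch

    def forward(self, features):
        outs = []
        for feat, box_b, cls_b in zip(features, self.box_branches, self.cls_branches):
            box = feat
            for layer in box_b:
                box = layer(box)
            cls = feat
            for layer in cls_b:
                cls = layer(cls)
            outs.append(np.concatenate([box, cls], axis=0))
        return outs
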