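"""Detector architecture assembly and accounting.

Two variants are buildable:

* ``baseline`` — a standard YOLOv8-n graph (width 0.25 / depth 0.33):
  P1-P5 backbone with SPPF, PAN neck, decoupled heads at strides 8/16/32.
* ``maize`` — the seedling-adapted graph: the stride-32 backbone stage and
  the large-object head are removed, the SPPF sits at stride 16 and widens
  128 -> 256, a bi-level routing attention block follows the SPPF, every
  C2f bottleneck is replaced by an SC block, and detection heads run at
  strides 4/8/16 (160/80/40 maps at 640 input) with reduced widths.

``use_scconv`` / ``use_biformer`` can override the variant defaults to
build the intermediate ablation models. Models are untrained structural
artifacts: the parameter and FLOP budgets and the head map shapes are the
verifiable quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import SPPF, BiFormerBlock, C2f, Conv, Detect
from .nn import Module, Profiler, upsample_nearest2x

__all__ = ["ArchConfig", "ArchSummary", "build_model", "summarize", "layer_table"]


@dataclass
class ArchConfig:
    """Configuration of the detector graph.

    ``head_strides`` and ``head_channels`` default per variant: 8/16/32
    with widths 64/128/256 for the baseline, 4/8/16 with widths 32/64/128
    for the maize variant (the calibrated widths that land the printed
    parameter budget). ``biformer`` is (dim, n_heads, region_grid, top_k).
    """

    variant: str = "maize"
    num_classes: int = 1
    input_size: int = 640
    width_mult: float = 0.25
    depth_mult: float = 0.33
    use_scconv: bool | None = None
    use_biformer: bool | None = None
    head_strides: tuple[int, ...] = None
    head_channels: tuple[int, ...] = None
    biformer: tuple[int, int, int, int] = (256, 8, 4, 4)

    def __post_init__(self):
        if self.variant not in ("baseline", "maize"):
            raise ValueError("variant must be 'baseline' or 'maize'")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        defaults = {
            "baseline": ((8, 16, 32), (64, 128, 256), False, False),
            "maize": ((4, 8, 16), (32, 64, 128), True, True),
        }[self.variant]
        if self.head_strides is None:
            self.head_strides = defaults[0]
        if self.head_channels is None:
            self.head_channels = defaults[1]
        if self.use_scconv is None:
            self.use_scconv = defaults[2]
        if self.use_biformer is None:
            self.use_biformer = defaults[3]
        if self.input_size % max(self.head_strides):
            raise ValueError(
                f"input_size {self.input_size} not divisible by the largest stride {max(self.head_strides)}"
            )


@dataclass
class ArchSummary:
    params_millions: float
    gflops: float
    output_map_sizes: list[tuple[int, int]]
    params_exact: int = 0
    variant: str = ""

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params_millions": self.params_millions,
            "params_exact": self.params_exact,
            "gflops": self.gflops,
            "flops_convention": "2x multiply-accumulates of conv/linear layers",
            "output_map_sizes": [list(s) for s in self.output_map_sizes],
        }


class BaselineNet(Module):
    """YOLOv8-n graph: P5 backbone + PAN neck + strides 8/16/32 heads."""

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator):
        sc = cfg.use_scconv
        self.stem0 = Conv(3, 16, 3, stride=2, rng=rng)
        self.stem1 = Conv(16, 32, 3, stride=2, rng=rng)
        self.c2f_p2 = C2f(32, 32, 1, shortcut=True, scconv=sc, rng=rng)
        self.down3 = Conv(32, 64, 3, stride=2, rng=rng)
        self.c2f_p3 = C2f(64, 64, 2, shortcut=True, scconv=sc, rng=rng)
        self.down4 = Conv(64, 128, 3, stride=2, rng=rng)
        self.c2f_p4 = C2f(128, 128, 2, shortcut=True, scconv=sc, rng=rng)
        self.down5 = Conv(128, 256, 3, stride=2, rng=rng)
        self.c2f_p5 = C2f(256, 256, 1, shortcut=True, scconv=sc, rng=rng)
        self.sppf = SPPF(256, 256, rng=rng)
        self.attn = BiFormerBlock(*cfg.biformer, rng=rng) if cfg.use_biformer else None
        self.n4_td = C2f(384, 128, 1, scconv=sc, rng=rng)
        self.n3_td = C2f(192, 64, 1, scconv=sc, rng=rng)
        self.down_n3 = Conv(64, 64, 3, stride=2, rng=rng)
        self.n4_bu = C2f(192, 128, 1, scconv=sc, rng=rng)
        self.down_n4 = Conv(128, 128, 3, stride=2, rng=rng)
        self.n5_bu = C2f(384, 256, 1, scconv=sc, rng=rng)
        self.detect = Detect(cfg.head_channels, cfg.num_classes, rng=rng)

    def forward(self, x):
        x = self.stem1(self.stem0(x))
        p2 = self.c2f_p2(x)
        p3 = self.c2f_p3(self.down3(p2))
        p4 = self.c2f_p4(self.down4(p3))
        p5 = self.sppf(self.c2f_p5(self.down5(p4)))
        if self.attn is not None:
            p5 = self.attn(p5)
        t4 = self.n4_td(np.concatenate([upsample_nearest2x(p5), p4], axis=0))
        t3 = self.n3_td(np.concatenate([upsample_nearest2x(t4), p3], axis=0))
        b4 = self.n4_bu(np.concatenate([self.down_n3(t3), t4], axis=0))
        b5 = self.n5_bu(np.concatenate([self.down_n4(b4), p5], axis=0))
        return self.detect([t3, b4, b5])


class MaizeNet(Module):
    """P4-truncated graph with a stride-4 small-object head."""

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator):
        sc = cfg.use_scconv
        self.stem0 = Conv(3, 16, 3, stride=2, rng=rng)
        self.stem1 = Conv(16, 32, 3, stride=2, rng=rng)
        self.c2f_p2 = C2f(32, 32, 1, shortcut=True, scconv=sc, rng=rng)
        self.down3 = Conv(32, 64, 3, stride=2, rng=rng)
        self.c2f_p3 = C2f(64, 64, 2, shortcut=True, scconv=sc, rng=rng)
        self.down4 = Conv(64, 128, 3, stride=2, rng=rng)
        self.c2f_p4 = C2f(128, 128, 2, shortcut=True, scconv=sc, rng=rng)
        self.sppf = SPPF(128, 256, rng=rng)
        self.attn = BiFormerBlock(*cfg.biformer, rng=rng) if cfg.use_biformer else None
        self.n3_td = C2f(320, 64, 1, scconv=sc, rng=rng)
        self.n2_td = C2f(96, 32, 1, scconv=sc, rng=rng)
        self.down_n2 = Conv(32, 32, 3, stride=2, rng=rng)
        self.n3_bu = C2f(96, 64, 1, scconv=sc, rng=rng)
        self.down_n3 = Conv(64, 64, 3, stride=2, rng=rng)
        self.n4_bu = C2f(320, 128, 1, scconv=sc, rng=rng)
        self.detect = Detect(cfg.head_channels, cfg.num_classes, rng=rng)

    def forward(self, x):
        x = self.stem1(self.stem0(x))
        p2 = self.c2f_p2(x)
        p3 = self.c2f_p3(self.down3(p2))
        p4 = self.sppf(self.c2f_p4(self.down4(p3)))
        if self.attn is not None:
            p4 = self.attn(p4)
        t3 = self.n3_td(np.concatenate([upsample_nearest2x(p4), p3], axis=0))
        t2 = self.n2_td(np.concatenate([upsample_nearest2x(t3), p2], axis=0))
        b3 = self.n3_bu(np.concatenate([self.down_n2(t2), t3], axis=0))
        b4 = self.n4_bu(np.concatenate([self.down_n3(b3), p4], axis=0))
        return self.detect([t2, b3, b4])


def build_model(cfg: ArchConfig, seed: int = 0) -> Module:
    """Instantiate the configured variant with deterministic weights."""
    rng = np.random.default_rng(seed)
    model = {"baseline": BaselineNet, "maize": MaizeNet}[cfg.variant](cfg, rng)
    model.cfg = cfg  # type: ignore[attr-defined]
    return model


def summarize(model: Module, cfg: ArchConfig | None = None) -> ArchSummary:
    """Parameter count (trainable scalars, millions to two decimals) and
    FLOPs (2 x conv/linear MACs on one ``input_size`` square frame, GFLOPs
    to one decimal) plus the per-head output map sizes."""
    cfg = cfg or model.cfg
    params = model.param_count(trainable_only=True)
    x = np.zeros((3, cfg.input_size, cfg.input_size), dtype=np.float32)
    with Profiler() as prof:
        heads = model(x)
    sizes = [tuple(h.shape[1:]) for h in heads]
    gflops = 2 * prof.macs / 1e9
    return ArchSummary(
        params_millions=round(params / 1e6, 2),
        gflops=round(gflops, 1),
        output_map_sizes=sizes,
        params_exact=params,
        variant=cfg.variant,
    )


def layer_table(model: Module) -> str:
    """Text table of the model's top-level layers and their parameters."""
    lines = [f"{'layer':<12} {'type':<16} {'params':>10}"]
    total = 0
    for name, value in model.__dict__.items():
        if isinstance(value, Module):
            n = value.param_count()
            total += n
            lines.append(f"{name:<12} {type(value).__name__:<16} {n:>10}")
    lines.append(f"{'total':<12} {'':<16} {total:>10}")
    return "\n".join(lines)
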