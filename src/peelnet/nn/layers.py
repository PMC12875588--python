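"""Composable layers over flat parameter trees.

Each layer owns a dotted name prefix inside the parameter dict.  ``forward``
returns the activation plus an opaque cache; ``backward`` consumes the cache,
accumulates parameter gradients into a grads dict, and returns the input
gradient.  Everything is float32 and functional: layers hold structure only,
never weights, so a single layer object can be evaluated under many
parameter trees (which is what the meta-learner needs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ops
from .ptree import ParamTree

DTYPE = np.float32


class Conv:
    def __init__(self, name: str, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0):
        self.name, self.cin, self.cout, self.k, self.stride, self.pad = name, cin, cout, k, stride, pad

    def init(self, params: ParamTree, rng: np.random.Generator) -> None:
        fan_in = self.cin * self.k * self.k
        std = np.sqrt(2.0 / fan_in)
        params[self.name + ".w"] = rng.normal(0, std, (self.cout, self.cin, self.k, self.k)).astype(DTYPE)
        params[self.name + ".b"] = np.zeros(self.cout, dtype=DTYPE)

    def forward(self, p: ParamTree, x):
        return ops.conv2d_forward(x, p[self.name + ".w"], p[self.name + ".b"], self.stride, self.pad)

    def backward(self, p: ParamTree, dy, cache, grads: ParamTree):
        dx, dw, db = ops.conv2d_backward(dy, cache)
        grads[self.name + ".w"] = grads.get(self.name + ".w", 0) + dw
        grads[self.name + ".b"] = grads.get(self.name + ".b", 0) + db
        return dx


def _num_groups(c: int, preferred: int = 4) -> int:
    for g in range(min(preferred, c), 0, -1):
        if c % g == 0:
            return g
    return 1


class GroupNorm:
    def __init__(self, name: str, channels: int, groups: int | None = None, zero_init: bool = False):
        self.name = name
        self.channels = channels
        self.groups = groups if groups is not None else _num_groups(channels)
        # Zero-initialized gain makes a residual branch start as identity,
        # which stabilizes from-scratch training of small residual nets.
        self.zero_init = zero_init

    def init(self, params: ParamTree, rng: np.random.Generator) -> None:
        fill = 0.0 if self.zero_init else 1.0
        params[self.name + ".g"] = np.full(self.channels, fill, dtype=DTYPE)
        params[self.name + ".b"] = np.zeros(self.channels, dtype=DTYPE)

    def forward(self, p: ParamTree, x):
        return ops.groupnorm_forward(x, p[self.name + ".g"], p[self.name + ".b"], self.groups)

    def backward(self, p: ParamTree, dy, cache, grads: ParamTree):
        dx, dg, db = ops.groupnorm_backward(dy, cache)
        grads[self.name + ".g"] = grads.get(self.name + ".g", 0) + dg
        grads[self.name + ".b"] = grads.get(self.name + ".b", 0) + db
        return dx


class Linear:
    def __init__(self, name: str, din: int, dout: int, std: float | None = None):
        self.name, self.din, self.dout = name, din, dout
        self.std = std if std is not None else np.sqrt(2.0 / din)

    def init(self, params: ParamTree, rng: np.random.Generator) -> None:
        params[self.name + ".w"] = rng.normal(0, self.std, (self.dout, self.din)).astype(DTYPE)
        params[self.name + ".b"] = np.zeros(self.dout, dtype=DTYPE)

    def forward(self, p: ParamTree, x):
        return ops.linear_forward(x, p[self.name + ".w"], p[self.name + ".b"])

    def backward(self, p: ParamTree, dy, cache, grads: ParamTree):
        dx, dw, db = ops.linear_backward(dy, cache)
        grads[self.name + ".w"] = grads.get(self.name + ".w", 0) + dw
        grads[self.name + ".b"] = grads.get(self.name + ".b", 0) + db
        return dx


class ResBlock:
    """Residual block; ``bottleneck=False`` gives the two-3x3 basic block,
    ``bottleneck=True`` the 1x1/3x3/1x1 block with 4x channel expansion.
    Every convolution is followed by group normalization."""

    def __init__(self, name: str, cin: int, width: int, stride: int, bottleneck: bool):
        self.name, self.bottleneck, self.stride = name, bottleneck, stride
        self.cout = width * (4 if bottleneck else 1)
        if bottleneck:
            self.convs = [
                Conv(name + ".c1", cin, width, 1),
                Conv(name + ".c2", width, width, 3, stride, 1),
                Conv(name + ".c3", width, self.cout, 1),
            ]
            norm_ch = [width, width, self.cout]
        else:
            self.convs = [
                Conv(name + ".c1", cin, width, 3, stride, 1),
                Conv(name + ".c2", width, self.cout, 3, 1, 1),
            ]
            norm_ch = [width, self.cout]
        self.norms = [GroupNorm(f"{name}.n{i + 1}", c) for i, c in enumerate(norm_ch)]
        if stride != 1 or cin != self.cout:
            self.proj = Conv(name + ".proj", cin, self.cout, 1, stride)
            self.proj_norm = GroupNorm(name + ".projn", self.cout)
        else:
            self.proj = None
            self.proj_norm = None

    def init(self, params: ParamTree, rng: np.random.Generator) -> None:
        for c in self.convs:
            c.init(params, rng)
        for nm in self.norms:
            nm.init(params, rng)
        if self.proj is not None:
            self.proj.init(params, rng)
            self.proj_norm.init(params, rng)

    def forward(self, p: ParamTree, x):
        caches = []
        h = x
        for i, (c, nm) in enumerate(zip(self.convs, self.norms)):
            h, cc = c.forward(p, h)
            h, nc = nm.forward(p, h)
            if i < len(self.convs) - 1:
                h, rm = ops.relu_forward(h)
            else:
                rm = None
            caches.append((cc, nc, rm))
        if self.proj is not None:
            sc, pc = self.proj.forward(p, x)
            sc, pnc = self.proj_norm.forward(p, sc)
        else:
            sc, pc, pnc = x, None, None
        y = h + sc
        y, rm_out = ops.relu_forward(y)
        return y, (caches, pc, pnc, rm_out)

    def backward(self, p: ParamTree, dy, cache, grads: ParamTree):
        caches, pc, pnc, rm_out = cache
        dy = ops.relu_backward(dy, rm_out)
        dh = dy
        for i in range(len(self.convs) - 1, -1, -1):
            cc, nc, rm = caches[i]
            if rm is not None:
                dh = ops.relu_backward(dh, rm)
            dh = self.norms[i].backward(p, dh, nc, grads)
            dh = self.convs[i].backward(p, dh, cc, grads)
        if self.proj is not None:
            dsc = self.proj_norm.backward(p, dy, pnc, grads)
            dsc = self.proj.backward(p, dsc, pc, grads)
        else:
            dsc = dy
        return dh + dsc


@dataclass(frozen=True)
class BackboneConfig:
    """Four-stage residual backbone specification.

    ``standard-50`` is the canonical 50-layer bottleneck network (stage widths
    64/128/256/512, block counts 3/4/6/3, 224x224 input, 2048-channel stage-4
    output at 7x7).  ``reduced`` is a desk-scale basic-block variant with the
    same four-stage layout and final global pooling, sized for 64x64 inputs.
    """

    variant: str = "reduced"
    widths: tuple[int, ...] = (8, 16, 32, 64)
    blocks: tuple[int, ...] = (1, 1, 1, 1)
    strides: tuple[int, ...] = (1, 2, 2, 2)
    bottleneck: bool = False
    input_size: int = 64
    in_channels: int = 3
    stem_pool: bool = False

    @staticmethod
    def standard50() -> "BackboneConfig":
        return BackboneConfig(
            variant="standard-50",
            widths=(64, 128, 256, 512),
            blocks=(3, 4, 6, 3),
            strides=(1, 2, 2, 2),
            bottleneck=True,
            input_size=224,
            stem_pool=True,
        )

    @staticmethod
    def reduced() -> "BackboneConfig":
        return BackboneConfig()

    @property
    def out_channels(self) -> int:
        return self.widths[-1] * (4 if self.bottleneck else 1)

    def stage_channels(self, stage: int) -> int:
        """Output channels after residual stage ``stage`` (1-based)."""
        return self.widths[stage - 1] * (4 if self.bottleneck else 1)


class Backbone:
    """Stem + four residual stages, evaluable stage-by-stage so a caller can
    splice channel-level interaction between stages."""

    def __init__(self, cfg: BackboneConfig, name: str = "bb"):
        self.cfg = cfg
        self.name = name
        stem_out = cfg.widths[0]
        if cfg.stem_pool:
            self.stem = Conv(name + ".stem", cfg.in_channels, stem_out, 7, 2, 3)
        else:
            self.stem = Conv(name + ".stem", cfg.in_channels, stem_out, 3, 2, 1)
        self.stem_norm = GroupNorm(name + ".stemn", stem_out)
        self.stages: list[list[ResBlock]] = []
        cin = stem_out
        for si in range(4):
            blocks = []
            for bi in range(cfg.blocks[si]):
                stride = cfg.strides[si] if bi == 0 else 1
                blk = ResBlock(f"{name}.s{si + 1}.b{bi}", cin, cfg.widths[si], stride, cfg.bottleneck)
                blocks.append(blk)
                cin = blk.cout
            self.stages.append(blocks)

    def init(self, params: ParamTree, rng: np.random.Generator) -> None:
        self.stem.init(params, rng)
        self.stem_norm.init(params, rng)
        for st in self.stages:
            for b in st:
                b.init(params, rng)

    def forward_stem(self, p: ParamTree, x):
        h, cc = self.stem.forward(p, x)
        h, nc = self.stem_norm.forward(p, h)
        h, rm = ops.relu_forward(h)
        mp = None
        if self.cfg.stem_pool:
            h, mp = ops.maxpool_forward(h, 3, 2, 1)
        return h, (cc, nc, rm, mp)

    def backward_stem(self, p: ParamTree, dy, cache, grads: ParamTree):
        cc, nc, rm, mp = cache
        if mp is not None:
            dy = ops.maxpool_backward(dy, mp)
        dy = ops.relu_backward(dy, rm)
        dy = self.stem_norm.backward(p, dy, nc, grads)
        return self.stem.backward(p, dy, cc, grads)

    def forward_stages(self, p: ParamTree, x, start: int, stop: int):
        """Run residual stages ``start``..``stop`` (1-based, inclusive)."""
        caches = []
        h = x
        for si in range(start - 1, stop):
            for b in self.stages[si]:
                h, c = b.forward(p, h)
                caches.append((b, c))
        return h, caches

    def backward_stages(self, p: ParamTree, dy, caches, grads: ParamTree):
        for b, c in reversed(caches):
            dy = b.backward(p, dy, c, grads)
        return dy
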