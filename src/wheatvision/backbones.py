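"""Backbone feature extractors for the segmentation encoder.

Each backbone maps an RGB batch to a pair of feature maps: a shallow
"low-level" map at 1/4 input resolution (used by the decoder's skip
connection) and the deep encoder output at 1/``output_stride`` resolution.
When the requested output stride is smaller than the backbone's nominal
downsampling, the final stage(s) trade stride for dilation so the receptive
field grows without further resolution loss.

``width_multiplier`` scales every channel count so the same topologies run
at desk scale; ``1.0`` reproduces the standard widths.  The ResNet stem's
max-pool is replaced by a stride-2 convolution (the common "ResNet-C"
variant) because the engine is convolution-only.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import ConvBNReLU, Module, Sequential
from .nn import autodiff as ad

__all__ = ["make_backbone", "BACKBONES"]


def _scale(c: int, wm: float) -> int:
    return max(1, int(round(c * wm)))


# ---------------------------------------------------------------------------
# tiny residual backbone (desk-scale testing)
# ---------------------------------------------------------------------------

class _BasicBlock(Module):
    def __init__(self, in_ch, out_ch, rng, stride=1, dilation=1):
        super().__init__()
        self.c1 = ConvBNReLU(in_ch, out_ch, 3, rng, stride=stride, dilation=dilation)
        self.c2 = ConvBNReLU(out_ch, out_ch, 3, rng, dilation=dilation, activation=None)
        self.proj = (
            ConvBNReLU(in_ch, out_ch, 1, rng, stride=stride, activation=None)
            if stride != 1 or in_ch != out_ch
            else None
        )

    def forward(self, x):
        y = self.c2(self.c1(x))
        skip = self.proj(x) if self.proj is not None else x
        return ad.relu(ad.add(y, skip))


class TinyBackbone(Module):
    """Four-stage residual net, nominal output stride 16."""

    def __init__(self, width_multiplier=1.0, output_stride=16, rng=None):
        super().__init__()
        w = [_scale(c, width_multiplier) for c in (16, 32, 64, 64)]
        self.stem = ConvBNReLU(3, w[0], 3, rng, stride=2)
        self.stage1 = _BasicBlock(w[0], w[1], rng, stride=2)
        self.stage2 = _BasicBlock(w[1], w[2], rng, stride=2)
        if output_stride == 16:
            self.stage3 = _BasicBlock(w[2], w[3], rng, stride=2)
        else:  # output_stride 8: dilate instead of stride
            self.stage3 = _BasicBlock(w[2], w[3], rng, stride=1, dilation=2)
        self.low_channels = w[1]
        self.out_channels = w[3]

    def forward(self, x):
        low = self.stage1(self.stem(x))
        return low, self.stage3(self.stage2(low))


# ---------------------------------------------------------------------------
# ResNet-50 / ResNet-101
# ---------------------------------------------------------------------------

class _Bottleneck(Module):
    def __init__(self, in_ch, mid_ch, out_ch, rng, stride=1, dilation=1):
        super().__init__()
        self.c1 = ConvBNReLU(in_ch, mid_ch, 1, rng)
        self.c2 = ConvBNReLU(mid_ch, mid_ch, 3, rng, stride=stride, dilation=dilation)
        self.c3 = ConvBNReLU(mid_ch, out_ch, 1, rng, activation=None)
        self.proj = (
            ConvBNReLU(in_ch, out_ch, 1, rng, stride=stride, activation=None)
            if stride != 1 or in_ch != out_ch
            else None
        )

    def forward(self, x):
        y = self.c3(self.c2(self.c1(x)))
        skip = self.proj(x) if self.proj is not None else x
        return ad.relu(ad.add(y, skip))


class ResNetBackbone(Module):
    LAYERS = {50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}

    def __init__(self, depth, width_multiplier=1.0, output_stride=16, rng=None):
        super().__init__()
        blocks = self.LAYERS[depth]
        outs = [_scale(c, width_multiplier) for c in (256, 512, 1024, 2048)]
        mids = [_scale(c, width_multiplier) for c in (64, 128, 256, 512)]
        stem_ch = _scale(64, width_multiplier)
        self.stem = Sequential(
            ConvBNReLU(3, stem_ch, 7, rng, stride=2),
            ConvBNReLU(stem_ch, stem_ch, 3, rng, stride=2),  # stands in for max-pool
        )
        strides = [1, 2, 2, 2]
        dilations = [1, 1, 1, 1]
        if output_stride == 16:
            strides[3], dilations[3] = 1, 2
        elif output_stride == 8:
            strides[2], dilations[2] = 1, 2
            strides[3], dilations[3] = 1, 4
        stages = []
        in_ch = stem_ch
        for n_blocks, mid, out, s, d in zip(blocks, mids, outs, strides, dilations):
            blocks_i = [_Bottleneck(in_ch, mid, out, rng, stride=s, dilation=d)]
            blocks_i += [
                _Bottleneck(out, mid, out, rng, dilation=d) for _ in range(n_blocks - 1)
            ]
            stages.append(Sequential(*blocks_i))
            in_ch = out
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.low_channels = outs[0]
        self.out_channels = outs[3]

    def forward(self, x):
        low = self.stage1(self.stem(x))
        return low, self.stage4(self.stage3(self.stage2(low)))


# ---------------------------------------------------------------------------
# MobileNetV2
# ---------------------------------------------------------------------------

class _InvertedResidual(Module):
    def __init__(self, in_ch, out_ch, rng, stride=1, expand=6, dilation=1):
        super().__init__()
        hidden = in_ch * expand
        self.use_res = stride == 1 and in_ch == out_ch
        layers = []
        if expand != 1:
            layers.append(ConvBNReLU(in_ch, hidden, 1, rng, activation="relu6"))
        layers.append(
            ConvBNReLU(
                hidden, hidden, 3, rng,
                stride=stride, dilation=dilation, groups=hidden, activation="relu6",
            )
        )
        layers.append(ConvBNReLU(hidden, out_ch, 1, rng, activation=None))
        self.body = Sequential(*layers)

    def forward(self, x):
        y = self.body(x)
        return ad.add(y, x) if self.use_res else y


class MobileNetV2Backbone(Module):
    # (expansion t, channels c, repeats n, stride s)
    CFG = [
        (1, 16, 1, 1),
        (6, 24, 2, 2),
        (6, 32, 3, 2),
        (6, 64, 4, 2),
        (6, 96, 3, 1),
        (6, 160, 3, 2),
        (6, 320, 1, 1),
    ]

    def __init__(self, width_multiplier=1.0, output_stride=16, rng=None):
        super().__init__()
        wm = width_multiplier
        stem_ch = _scale(32, wm)
        self.stem = ConvBNReLU(3, stem_ch, 3, rng, stride=2, activation="relu6")
        in_ch = stem_ch
        current_stride, dilation = 2, 1
        self.low_blocks: list[Module] = []
        self.high_blocks: list[Module] = []
        low_done = False
        for t, c, n, s in self.CFG:
            out_ch = _scale(c, wm)
            for i in range(n):
                stride = s if i == 0 else 1
                if stride == 2 and current_stride >= output_stride:
                    stride, dil = 1, dilation * 2
                    dilation = dil
                else:
                    dil = dilation
                    if stride == 2:
                        current_stride *= 2
                block = _InvertedResidual(
                    in_ch, out_ch, rng, stride=stride, expand=t, dilation=dil
                )
                (self.high_blocks if low_done else self.low_blocks).append(block)
                in_ch = out_ch
            if current_stride == 4 and not low_done:
                low_done = True
                self.low_channels = in_ch
        self.out_channels = in_ch

    def forward(self, x):
        y = self.stem(x)
        for b in self.low_blocks:
            y = b(y)
        low = y
        for b in self.high_blocks:
            y = b(y)
        return low, y


# ---------------------------------------------------------------------------
# Xception-65
# ---------------------------------------------------------------------------

class _SepConv(Module):
    """Depthwise 3x3 + pointwise 1x1, each batch-normalised."""

    def __init__(self, in_ch, out_ch, rng, stride=1, dilation=1, activation="relu"):
        super().__init__()
        self.dw = ConvBNReLU(
            in_ch, in_ch, 3, rng, stride=stride, dilation=dilation, groups=in_ch
        )
        self.pw = ConvBNReLU(in_ch, out_ch, 1, rng, activation=activation)

    def forward(self, x):
        return self.pw(self.dw(x))


class _XceptionBlock(Module):
    def __init__(self, in_ch, out_ch, rng, stride=1, dilation=1):
        super().__init__()
        self.s1 = _SepConv(in_ch, out_ch, rng, dilation=dilation)
        self.s2 = _SepConv(out_ch, out_ch, rng, dilation=dilation)
        self.s3 = _SepConv(out_ch, out_ch, rng, stride=stride, dilation=dilation,
                           activation=None)
        self.proj = (
            ConvBNReLU(in_ch, out_ch, 1, rng, stride=stride, activation=None)
            if stride != 1 or in_ch != out_ch
            else None
        )

    def forward(self, x):
        y = self.s3(self.s2(self.s1(x)))
        skip = self.proj(x) if self.proj is not None else x
        return ad.relu(ad.add(y, skip))


class Xception65Backbone(Module):
    """Entry/middle/exit-flow depthwise-separable backbone (65-conv layout)."""

    def __init__(self, width_multiplier=1.0, output_stride=16, rng=None):
        super().__init__()
        w = lambda c: _scale(c, width_multiplier)
        self.entry_stem = Sequential(
            ConvBNReLU(3, w(32), 3, rng, stride=2),
            ConvBNReLU(w(32), w(64), 3, rng),
        )
        self.entry1 = _XceptionBlock(w(64), w(128), rng, stride=2)  # stride 4
        self.entry2 = _XceptionBlock(w(128), w(256), rng, stride=2)  # stride 8
        if output_stride == 16:
            self.entry3 = _XceptionBlock(w(256), w(728), rng, stride=2)
            exit_dil = 2
        else:  # 8
            self.entry3 = _XceptionBlock(w(256), w(728), rng, stride=1, dilation=2)
            exit_dil = 4
        self.middle = Sequential(
            *[_XceptionBlock(w(728), w(728), rng, dilation=exit_dil // 2 or 1)
              for _ in range(16)]
        )
        self.exit1 = _XceptionBlock(w(728), w(1024), rng, stride=1, dilation=exit_dil)
        self.exit2 = Sequential(
            _SepConv(w(1024), w(1536), rng, dilation=exit_dil),
            _SepConv(w(1536), w(2048), rng, dilation=exit_dil),
        )
        self.low_channels = w(128)
        self.out_channels = w(2048)

    def forward(self, x):
        low = self.entry1(self.entry_stem(x))
        y = self.entry3(self.entry2(low))
        y = self.exit2(self.exit1(self.middle(y)))
        return low, y


BACKBONES = {
    "tiny": TinyBackbone,
    "resnet50": lambda **kw: ResNetBackbone(50, **kw),
    "resnet101": lambda **kw: ResNetBackbone(101, **kw),
    "mobilenetv2": MobileNetV2Backbone,
    "xception65": Xception65Backbone,
}


def make_backbone(name: str, width_multiplier: float, output_stride: int,
                  rng: np.random.Generator) -> Module:
    try:
        factory = BACKBONES[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}"
        ) from None
    return factory(width_multiplier=width_multiplier, output_stride=output_stride,
                   rng=rng)
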