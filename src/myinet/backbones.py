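"""Backbone feature extractors: MI-ResNet (18/50) and MI-MobileNet.

Each backbone maps a single-channel image to a pair of feature grids:

* low-level features at 1/4 of the input resolution, tapped at the end of
  the stride-4 stage (fine spatial detail for the decoder), and
* high-level features at 1/16 resolution (output stride 16): the final stage
  trades its stride for atrous convolution so that the context module that
  follows still sees a non-collapsed grid.

The residual family composes blocks R_l = sigma(H_l(x) + shortcut(x)); with
the transform branch H_l zeroed and an identity shortcut a block reduces to
the identity on non-negative inputs, and dropping the shortcut gives the
plain cascade of a conventional CNN.  The MobileNet family is built from
depthwise separable convolutions and inverted residual bottlenecks (1x1
expansion with capped rectification, 3x3 depthwise, linear 1x1 projection,
skip only at stride 1 with matching channels).

The width multiplier (epsilon) uniformly thins every stage's channel count;
the resolution multiplier (delta) shrinks the consumed input image.  Both
are honoured for all backbones; for the residual family the width knob is a
desk-scale convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Identity, MaxPool2d, Module, ReLU,
                 ReLU6, Sequential, Tensor)
from .nn import functional as F

__all__ = [
    "ModelSpec",
    "FeatureExtractor",
    "ResidualBlock",
    "BottleneckResidualBlock",
    "DepthwiseSeparableConv",
    "InvertedResidual",
    "residual_block",
    "build_resnet",
    "build_mobilenetv2",
    "build_backbone",
    "dsc_cost",
]

BACKBONES = ("mi-resnet18", "mi-resnet50", "mi-mobilenetv2")


@dataclass
class ModelSpec:
    """Architecture configuration shared by backbones and the full model."""

    backbone: str = "mi-resnet18"
    n_classes: int = 4
    atrous_base_rate: int = 6
    width_multiplier: float = 1.0
    resolution_multiplier: float = 1.0
    output_stride: int = 16
    aspp_channels: int = 256

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width multiplier must be in (0, 1]")
        if not 0.0 < self.resolution_multiplier <= 1.0:
            raise ValueError("resolution multiplier must be in (0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.output_stride != 16:
            raise ValueError("only output stride 16 is supported")

    def channels(self, c: int) -> int:
        """Apply the width multiplier: round to the nearest integer, min 1."""
        return max(1, round(self.width_multiplier * c))


def _cbr(c_in, c_out, k, rng, *, stride=1, dilation=1, relu6=False, groups=1):
    pad = dilation * (k - 1) // 2
    act = ReLU6() if relu6 else ReLU()
    return Sequential(Conv2d(c_in, c_out, k, rng, stride=stride, padding=pad,
                             dilation=dilation, groups=groups),
                      BatchNorm2d(c_out), act)


class FeatureExtractor(Module):
    """Image -> (low-level grid at H/4, high-level grid at H/16)."""

    def __init__(self, backbone_name: str, resolution_multiplier: float = 1.0):
        super().__init__()
        self.backbone_name = backbone_name
        self.resolution_multiplier = resolution_multiplier
        self.low_level_channels = 0
        self.high_level_channels = 0

    def consumed_size(self, h: int, w: int) -> tuple[int, int]:
        """Spatial size after the resolution multiplier is applied."""
        d = self.resolution_multiplier
        if d >= 1.0:
            return h, w
        return max(16, int(round(d * h))), max(16, int(round(d * w)))

    def _maybe_shrink(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[-2:]
        ch, cw = self.consumed_size(h, w)
        if (ch, cw) != (h, w):
            x = F.resize_bilinear(x, (ch, cw))
        return x


class ResidualBlock(Module):
    """Two-convolution basic residual block: out = relu(H(x) + shortcut(x))."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, *,
                 stride: int = 1, dilation: int = 1):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        pad = dilation
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride, padding=pad,
                            dilation=dilation)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, padding=pad, dilation=dilation)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, rng, stride=stride),
                                       BatchNorm2d(c_out))
        else:
            self.shortcut = Identity()

    def forward(self, x):
        h = F.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        return F.relu(F.add(h, self.shortcut(x)))


def residual_block(x, block: ResidualBlock):
    """Apply a residual block to a feature grid (thin functional wrapper)."""
    return block(x if isinstance(x, Tensor) else Tensor(x))


class BottleneckResidualBlock(Module):
    """1x1 / 3x3 / 1x1 bottleneck residual block (expansion 4)."""

    expansion = 4

    def __init__(self, c_in: int, c_mid: int, rng: np.random.Generator, *,
                 stride: int = 1, dilation: int = 1):
        super().__init__()
        c_out = c_mid * self.expansion
        self.conv1 = Conv2d(c_in, c_mid, 1, rng)
        self.bn1 = BatchNorm2d(c_mid)
        self.conv2 = Conv2d(c_mid, c_mid, 3, rng, stride=stride,
                            padding=dilation, dilation=dilation)
        self.bn2 = BatchNorm2d(c_mid)
        self.conv3 = Conv2d(c_mid, c_out, 1, rng)
        self.bn3 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, rng, stride=stride),
                                       BatchNorm2d(c_out))
        else:
            self.shortcut = Identity()
        self.out_channels = c_out

    def forward(self, x):
        h = F.relu(self.bn1(self.conv1(x)))
        h = F.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        return F.relu(F.add(h, self.shortcut(x)))


class DepthwiseSeparableConv(Module):
    """Per-channel 3x3 convolution then 1x1 pointwise, each with BN + ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, *,
                 stride: int = 1, dilation: int = 1):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel_size = 3
        self.depthwise = _cbr(c_in, c_in, 3, rng, stride=stride,
                              dilation=dilation, groups=c_in)
        self.pointwise = _cbr(c_in, c_out, 1, rng)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))

    def multiply_count(self, feature_size: int) -> int:
        """Multiplies performed on a square feature map of the given side
        (unit stride, same padding): depthwise + pointwise stages."""
        f2 = feature_size * feature_size
        return (self.c_in * self.kernel_size ** 2 * f2
                + self.c_in * self.c_out * f2)


def dsc_cost(d_i: int, d_o: int, d_f: int, d_k: int = 1,
             epsilon: float = 1.0, delta: float = 1.0) -> float:
    """Multiply count of one depthwise separable convolution.

    ``epsilon`` thins the channel counts (rounded to the nearest integer,
    minimum 1) and ``delta`` shrinks the feature map.  With ``d_k = 1`` this
    is the two-term multiplier cost formula in its printed form; passing the
    true depthwise kernel size (3 for the 3x3 filters used here) gives the
    kernel-corrected count.  Reports should state both.
    """
    if d_i <= 0 or d_o <= 0 or d_f <= 0 or d_k <= 0:
        raise ValueError("all size arguments must be positive")
    if not 0.0 < epsilon <= 1.0 or not 0.0 < delta <= 1.0:
        raise ValueError("multipliers must be in (0, 1]")
    c_in = max(1, round(epsilon * d_i))
    c_out = max(1, round(epsilon * d_o))
    f = delta * d_f
    return float(c_in * d_k ** 2 * f * f + c_in * c_out * f * f)


class InvertedResidual(Module):
    """MobileNetV2 bottleneck: expand (ReLU6) -> depthwise -> linear project.

    The additive skip is present iff stride == 1 and the channel count is
    preserved; the projection has no nonlinearity.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, *,
                 expansion: int = 6, stride: int = 1, dilation: int = 1):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        hidden = c_in * expansion
        self.use_skip = stride == 1 and c_in == c_out
        layers = []
        if expansion != 1:
            layers.append(_cbr(c_in, hidden, 1, rng, relu6=True))
        layers.append(_cbr(hidden, hidden, 3, rng, stride=stride,
                           dilation=dilation, relu6=True, groups=hidden))
        layers.append(Sequential(Conv2d(hidden, c_out, 1, rng),
                                 BatchNorm2d(c_out)))
        self.body = Sequential(*layers)

    def forward(self, x):
        h = self.body(x)
        return F.add(h, x) if self.use_skip else h


# ---------------------------------------------------------------------------
# backbone assembly
# ---------------------------------------------------------------------------


class _ResNet(FeatureExtractor):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec.backbone, spec.resolution_multiplier)
        ch = spec.channels
        deep = spec.backbone == "mi-resnet50"
        counts = (3, 4, 6, 3) if deep else (2, 2, 2, 2)
        widths = (64, 128, 256, 512)

        self.stem = Sequential(
            Conv2d(1, ch(64), 7, rng, stride=2, padding=3),
            BatchNorm2d(ch(64)), ReLU(), MaxPool2d(3, 2, 1))

        def make_stage(c_in, width, n_blocks, stride, dilation):
            blocks = []
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                if deep:
                    blk = BottleneckResidualBlock(c_in, ch(width), rng, stride=s,
                                                  dilation=dilation)
                    c_in = blk.out_channels
                else:
                    blk = ResidualBlock(c_in, ch(width), rng, stride=s,
                                        dilation=dilation)
                    c_in = ch(width)
                blocks.append(blk)
            return Sequential(*blocks), c_in

        c = ch(64)
        self.stage1, c = make_stage(c, widths[0], counts[0], 1, 1)
        self.low_level_channels = c
        self.stage2, c = make_stage(c, widths[1], counts[1], 2, 1)
        self.stage3, c = make_stage(c, widths[2], counts[2], 2, 1)
        # final stage keeps stride 16 by dilating instead of striding
        self.stage4, c = make_stage(c, widths[3], counts[3], 1, 2)
        self.high_level_channels = c

    def forward(self, x):
        x = self._maybe_shrink(x if isinstance(x, Tensor) else Tensor(x))
        x = self.stem(x)
        low = self.stage1(x)
        x = self.stage2(low)
        x = self.stage3(x)
        high = self.stage4(x)
        return low, high


#: MobileNetV2 stage table: (expansion, channels, repeats, stride)
_MOBILENET_STAGES = ((1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2),
                     (6, 64, 4, 2), (6, 96, 3, 1), (6, 160, 3, 2),
                     (6, 320, 1, 1))


class _MobileNetV2(FeatureExtractor):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec.backbone, spec.resolution_multiplier)
        ch = spec.channels
        self.stem = _cbr(1, ch(32), 3, rng, stride=2, relu6=True)

        stages = []
        c_in = ch(32)
        current_stride = 2
        dilation = 1
        self._tap_stage = None
        for idx, (t, c, n, s) in enumerate(_MOBILENET_STAGES):
            c_out = ch(c)
            blocks = []
            for b in range(n):
                stride = s if b == 0 else 1
                if stride == 2 and current_stride >= 16:
                    # hold output stride at 16: dilate instead of stride
                    stride, block_dil = 1, dilation * 2
                    dilation = block_dil
                else:
                    block_dil = dilation
                    if stride == 2:
                        current_stride *= 2
                blocks.append(InvertedResidual(c_in, c_out, rng, expansion=t,
                                               stride=stride, dilation=block_dil))
                c_in = c_out
            stages.append(Sequential(*blocks))
            if current_stride == 4 and self._tap_stage is None and dilation == 1:
                self._tap_stage = idx
                self.low_level_channels = c_in
        self.stages = stages
        self.high_level_channels = c_in

    def forward(self, x):
        x = self._maybe_shrink(x if isinstance(x, Tensor) else Tensor(x))
        x = self.stem(x)
        low = None
        for idx, stage in enumerate(self.stages):
            x = stage(x)
            if idx == self._tap_stage:
                low = x
        return low, x


def build_resnet(spec: ModelSpec, seed: int = 0) -> FeatureExtractor:
    """Build an MI-ResNet feature extractor (18 or 50 layers)."""
    if spec.backbone not in ("mi-resnet18", "mi-resnet50"):
        raise ValueError(f"build_resnet cannot build {spec.backbone!r}")
    return _ResNet(spec, np.random.default_rng(seed))


def build_mobilenetv2(spec: ModelSpec, seed: int = 0) -> FeatureExtractor:
    """Build the MI-MobileNet (MobileNetV2) feature extractor."""
    if spec.backbone != "mi-mobilenetv2":
        raise ValueError(f"build_mobilenetv2 cannot build {spec.backbone!r}")
    return _MobileNetV2(spec, np.random.default_rng(seed))


def build_backbone(spec: ModelSpec, seed: int = 0) -> FeatureExtractor:
    if spec.backbone == "mi-mobilenetv2":
        return build_mobilenetv2(spec, seed)
    return build_resnet(spec, seed)
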