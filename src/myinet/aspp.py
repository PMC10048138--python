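"""Atrous (dilated) convolution and atrous spatial pyramid pooling (ASPP).

An atrous convolution with rate k samples the input with gaps of k-1 pixels
between filter taps:

    h_i = sum_n f_{i + k*n} * w_n        (taps centred on i)

which enlarges the receptive field of an n-tap kernel to n + (n-1)(k-1)
pixels while keeping the parameter count constant; at k = 1 it reverts to a
conventional convolution.

The ASPP block runs four parallel branches over the high-level feature map --
a 1x1 convolution and three 3x3 atrous convolutions at rates (k, 2k, 3k),
each followed by batch normalisation and rectification -- and fuses them by
channel concatenation followed by a 1x1 projection.  The default base rate
is k = 6, giving branch rates (6, 12, 18).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, ReLU, Sequential

__all__ = ["AsppSpec", "atrous_conv", "effective_receptive_field", "build_aspp",
           "Aspp"]


@dataclass
class AsppSpec:
    in_channels: int
    branch_channels: int = 256
    base_rate: int = 6

    def __post_init__(self):
        if self.base_rate < 1:
            raise ValueError("base rate must be >= 1")
        if self.in_channels < 1 or self.branch_channels < 1:
            raise ValueError("channel counts must be positive")

    @property
    def rates(self) -> tuple[int, int, int]:
        k = self.base_rate
        return (k, 2 * k, 3 * k)


def atrous_conv(f, w, k: int):
    """Dilated cross-correlation with centred taps and zero same-padding.

    ``f`` may be 1-D or 2-D.  A 1-D filter on a 2-D input is applied
    separably along both spatial axes; a 2-D filter is applied as a full 2-D
    stencil.  Output has the input's shape.
    """
    if k < 1:
        raise ValueError("dilation rate must be >= 1")
    f = np.asarray(f, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if f.ndim == 1:
        if w.ndim != 1:
            raise ValueError("1-D input needs a 1-D filter")
        return _atrous_1d(f, w, k)
    if f.ndim == 2:
        if w.ndim == 1:
            out = np.stack([_atrous_1d(row, w, k) for row in f])
            return np.stack([_atrous_1d(col, w, k) for col in out.T]).T
        if w.ndim == 2:
            return _atrous_2d(f, w, k)
    raise ValueError("input must be 1-D or 2-D")


def _atrous_1d(f: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    n = w.size
    half = (n - 1) // 2
    pad = k * (n - 1)  # generous zero padding; centred taps
    fp = np.pad(f, pad)
    out = np.zeros_like(f)
    for t in range(n):
        offset = k * (t - half)
        out += w[t] * fp[pad + offset: pad + offset + f.size]
    return out


def _atrous_2d(f: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    nh, nw = w.shape
    pad = k * max(nh - 1, nw - 1)
    fp = np.pad(f, pad)
    out = np.zeros_like(f)
    hh, hw = (nh - 1) // 2, (nw - 1) // 2
    for a in range(nh):
        for b in range(nw):
            oy, ox = k * (a - hh), k * (b - hw)
            out += w[a, b] * fp[pad + oy: pad + oy + f.shape[0],
                                pad + ox: pad + ox + f.shape[1]]
    return out


def effective_receptive_field(n: int, k: int) -> int:
    """Span in pixels of an n-tap kernel dilated at rate k: n + (n-1)(k-1)."""
    if n % 2 == 0:
        raise ValueError("kernel size must be odd")
    if k < 1:
        raise ValueError("dilation rate must be >= 1")
    return n + (n - 1) * (k - 1)


class Aspp(Module):
    """Four-branch atrous spatial pyramid pooling with concat + 1x1 fusion."""

    def __init__(self, spec: AsppSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c_in, c_b = spec.in_channels, spec.branch_channels
        branches = [Sequential(Conv2d(c_in, c_b, 1, rng), BatchNorm2d(c_b), ReLU())]
        for rate in spec.rates:
            branches.append(Sequential(
                Conv2d(c_in, c_b, 3, rng, padding=rate, dilation=rate),
                BatchNorm2d(c_b), ReLU()))
        self.branches = branches
        self.project = Sequential(Conv2d(4 * c_b, c_b, 1, rng),
                                  BatchNorm2d(c_b), ReLU())

    def forward(self, x):
        from .nn import functional as F
        outs = [branch(x) for branch in self.branches]
        return self.project(F.concat(outs, axis=1))


def build_aspp(spec: AsppSpec, seed: int = 0) -> Aspp:
    """Construct an ASPP block with seeded initialisation."""
    return Aspp(spec, np.random.default_rng(seed))
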