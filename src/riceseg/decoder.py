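"""Redesigned decoder blocks: partial FPN fusion, Part-LKA, and B-gnConv.

The decoder receives the encoder's 4-level pyramid, projects every level
to a common width, fuses the lower three levels top-down while emitting
the deepest level straight from its lateral projection (partial FPN),
sharpens the finest fused map with Part Large Kernel Attention, and after
bilinear upsampling + concatenation mixes channels with a 1x1 fusion
convolution augmented by a bottlenecked recursive gated convolution.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["PFPNFuse", "ClassicFPNFuse", "PartLKA", "GnConv", "BGnConv"]


class PFPNFuse(nn.Module):
    """Partial feature-pyramid fusion.

    Each level gets a 1x1 lateral projection to width ``dim``.  The deepest
    level is emitted from its lateral alone; it still seeds the top-down
    chain, so levels 3..1 receive bilinearly upsampled deeper content by
    elementwise addition.  No smoothing convolutions follow — the learnable
    content is exactly the four projections.
    """

    def __init__(self, in_channels, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.laterals = nn.ModuleList(
            [nn.Conv2d(c, dim, 1, rng) for c in in_channels]
        )

    def forward(self, pyramid: list[Tensor]) -> list[Tensor]:
        if len(pyramid) != len(self.laterals):
            raise ValueError(f"expected {len(self.laterals)} pyramid levels, got {len(pyramid)}")
        lats = [lat(x) for lat, x in zip(self.laterals, pyramid)]
        fused = [None] * len(lats)
        fused[-1] = lats[-1]
        carry = lats[-1]
        for i in range(len(lats) - 2, -1, -1):
            h, w = lats[i].shape[-2:]
            carry = lats[i] + F.resize_bilinear(carry, h, w)
            fused[i] = carry
        return fused


class ClassicFPNFuse(nn.Module):
    """Top-down FPN as in the original design (comparison variant).

    With ``smooth=False`` the add-based pathway coincides with
    :class:`PFPNFuse`; ``smooth=True`` appends the original per-level 3x3
    output convolutions (including the top level, which the partial
    variant deliberately leaves untouched).
    """

    def __init__(self, in_channels, dim: int, rng: np.random.Generator, smooth: bool = True):
        super().__init__()
        self.fpn = PFPNFuse(in_channels, dim, rng)
        self.smooth = smooth
        if smooth:
            self.smoothers = nn.ModuleList(
                [nn.Conv2d(dim, dim, 3, rng, padding=1) for _ in in_channels]
            )

    @property
    def laterals(self):
        return self.fpn.laterals

    def forward(self, pyramid: list[Tensor]) -> list[Tensor]:
        fused = self.fpn(pyramid)
        if self.smooth:
            fused = [conv(x) for conv, x in zip(self.smoothers, fused)]
        return fused


class PartLKA(nn.Module):
    """Part Large Kernel Attention.

    The input is split channel-wise into two halves.  One half passes a
    depthwise convolution followed by a dilated depthwise convolution
    (dilation 3) that widens the receptive field; the other half passes a
    depthwise convolution only.  The halves are re-concatenated and a 1x1
    convolution forms a full-shape multiplicative attention map applied to
    the original input.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 dw_kernel: int = 5, dilated_kernel: int = 7, dilation: int = 3,
                 compose_dilated: bool = True):
        super().__init__()
        if channels % 2:
            raise ValueError("Part-LKA requires an even channel count")
        half = channels // 2
        self.channels = channels
        self.compose_dilated = compose_dilated
        dpad = dilation * (dilated_kernel - 1) // 2
        if compose_dilated:
            self.dw1 = nn.Conv2d(half, half, dw_kernel, rng,
                                 padding=dw_kernel // 2, groups=half)
        self.dw_dilated = nn.Conv2d(half, half, dilated_kernel, rng,
                                    padding=dpad, dilation=dilation, groups=half)
        self.dw2 = nn.Conv2d(half, half, dw_kernel, rng,
                             padding=dw_kernel // 2, groups=half)
        self.attn_conv = nn.Conv2d(channels, channels, 1, rng)

    def attention(self, x: Tensor) -> Tensor:
        half = self.channels // 2
        f1 = F.narrow(x, 1, 0, half)
        f2 = F.narrow(x, 1, half, half)
        b1 = self.dw_dilated(self.dw1(f1)) if self.compose_dilated else self.dw_dilated(f1)
        b2 = self.dw2(f2)
        return self.attn_conv(F.concat([b1, b2], axis=1))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return F.mul(self.attention(x), x)


class GnConv(nn.Module):
    """Recursive gated convolution (equal channel width at every step).

    An input projection doubles the channels and splits them into a
    carried feature ``p0`` and a gate source ``q0``; each recursion step
    multiplies the carried feature elementwise with a depthwise-convolved
    gate, with 1x1 projections refreshing the gate between steps; an
    output projection restores the input width.  Each gate is damped by
    ``gate_scale`` (default 1/3, as in the original recursive-gated
    design) so repeated elementwise products cannot blow up activation
    magnitudes.  Order 1 with ``gate_scale=1`` is exactly
    ``phi_out(f(q0) * p0)``.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 order: int = 2, dw_kernel: int = 3, gate_scale: float = 1.0 / 3.0):
        super().__init__()
        if order < 1:
            raise ValueError("order must be >= 1")
        self.channels = channels
        self.order = order
        self.gate_scale = gate_scale
        self.proj_in = nn.Conv2d(channels, 2 * channels, 1, rng)
        self.dws = nn.ModuleList(
            [nn.Conv2d(channels, channels, dw_kernel, rng,
                       padding=dw_kernel // 2, groups=channels)
             for _ in range(order)]
        )
        self.gates = nn.ModuleList(
            [nn.Conv2d(channels, channels, 1, rng) for _ in range(order - 1)]
        )
        self.proj_out = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        pq = self.proj_in(x)
        p = F.narrow(pq, 1, 0, c)
        q = F.narrow(pq, 1, c, c)
        p = F.mul(F.scale(self.dws[0](q), self.gate_scale), p)
        for k in range(1, self.order):
            u = self.gates[k - 1](p)
            p = F.mul(F.scale(self.dws[k](u), self.gate_scale), p)
        return self.proj_out(p)


class BGnConv(nn.Module):
    """Bottleneck recursive gated convolution.

    1x1 compression to ``bottleneck`` channels, gated-convolution
    recursion at the reduced width, then 1x1 expansion back — trading a
    little representational width for a much smaller parameter and
    compute footprint.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 bottleneck: int = 192, order: int = 3, dw_kernel: int = 3):
        super().__init__()
        if bottleneck >= channels:
            warnings.warn(
                f"bottleneck width {bottleneck} >= channels {channels}: "
                "not a compression", stacklevel=2
            )
        self.compress = nn.Conv2d(channels, bottleneck, 1, rng)
        # channel normalization keeps the gated products well-scaled
        self.norm = nn.LayerNorm(bottleneck)
        self.gnconv = GnConv(bottleneck, rng, order=order, dw_kernel=dw_kernel)
        self.expand = nn.Conv2d(bottleneck, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        z = self.compress(x)
        z = self.norm(z.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
        return self.expand(self.gnconv(z))
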