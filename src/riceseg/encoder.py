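"""MiT-B0 hierarchical Transformer encoder.

Four stages, each an overlapping patch embedding followed by stacked
(efficient self-attention + Mix-FFN) blocks, produce a feature pyramid at
strides 4/8/16/32 of the input.  Attention cost is kept linear-ish by
shortening the key/value sequence with a spatial reduction ratio R: a
strided RxR convolution shrinks the token grid by R along each axis
before keys and values are formed (an alternative length-wise N -> N/R
reduction by reshape + linear is available via ``sr_mode="length"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "StageConfig", "MIT_B0_STAGES", "tokens_to_map", "map_to_tokens",
    "OverlapPatchEmbed", "EfficientSelfAttention", "MixFFN",
    "TransformerBlock", "MiTEncoder",
]


@dataclass
class StageConfig:
    patch_size: int
    stride: int
    embed_dim: int
    depth: int
    num_heads: int
    sr_ratio: int
    mlp_ratio: int

    def __post_init__(self):
        if self.stride > self.patch_size:
            raise ValueError("patches must overlap: stride <= patch_size")
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        if self.sr_ratio < 1:
            raise ValueError("sr_ratio must be >= 1")


#: Standard MiT-B0 stage plan: dims (32, 64, 160, 256), two blocks per
#: stage, heads (1, 2, 5, 8), reduction ratios (8, 4, 2, 1), FFN expansion 4.
MIT_B0_STAGES: tuple[StageConfig, ...] = (
    StageConfig(7, 4, 32, 2, 1, 8, 4),
    StageConfig(3, 2, 64, 2, 2, 4, 4),
    StageConfig(3, 2, 160, 2, 5, 2, 4),
    StageConfig(3, 2, 256, 2, 8, 1, 4),
)


def map_to_tokens(x: Tensor) -> tuple[Tensor, int, int]:
    """(B, C, H, W) -> (B, H*W, C), returning the spatial shape."""
    b, c, h, w = x.shape
    return x.reshape(b, c, h * w).transpose(0, 2, 1), h, w


def tokens_to_map(x: Tensor, h: int, w: int) -> Tensor:
    """(B, H*W, C) -> (B, C, H, W)."""
    b, n, c = x.shape
    if n != h * w:
        raise ValueError(f"token count {n} does not match spatial shape {h}x{w}")
    return x.transpose(0, 2, 1).reshape(b, c, h, w)


class OverlapPatchEmbed(nn.Module):
    """Strided convolution tokenizer; patch windows overlap (stride < patch)."""

    def __init__(self, in_channels: int, cfg: StageConfig, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(
            in_channels, cfg.embed_dim, cfg.patch_size, rng,
            stride=cfg.stride, padding=cfg.patch_size // 2,
        )
        self.norm = nn.LayerNorm(cfg.embed_dim)

    def forward(self, x: Tensor) -> tuple[Tensor, int, int]:
        if min(x.shape[-2:]) < self.proj.kernel_size:
            raise ValueError(
                f"input {x.shape[-2:]} smaller than patch size {self.proj.kernel_size}"
            )
        y = self.proj(x)
        tokens, h, w = map_to_tokens(y)
        return self.norm(tokens), h, w


class EfficientSelfAttention(nn.Module):
    def __init__(self, cfg: StageConfig, rng: np.random.Generator,
                 dropout: float = 0.0, sr_mode: str = "spatial", seed: int = 0):
        super().__init__()
        c = cfg.embed_dim
        self.num_heads = cfg.num_heads
        self.head_dim = c // cfg.num_heads
        self.sr_ratio = cfg.sr_ratio
        if sr_mode not in ("spatial", "length"):
            raise ValueError(f"unknown sr_mode {sr_mode!r}")
        self.sr_mode = sr_mode
        self.q = nn.Linear(c, c, rng)
        self.kv = nn.Linear(c, 2 * c, rng)
        self.proj = nn.Linear(c, c, rng)
        if self.sr_ratio > 1:
            if sr_mode == "spatial":
                self.sr = nn.Conv2d(c, c, cfg.sr_ratio, rng, stride=cfg.sr_ratio)
            else:
                self.sr = nn.Linear(c * cfg.sr_ratio, c, rng)
            self.sr_norm = nn.LayerNorm(c)
        self.attn_drop = nn.Dropout(dropout, seed)
        self.proj_drop = nn.Dropout(dropout, seed + 1)

    def _reduce(self, x: Tensor, h: int, w: int) -> Tensor:
        if self.sr_ratio == 1:
            return x
        b, n, c = x.shape
        if self.sr_mode == "spatial":
            red = self.sr(tokens_to_map(x, h, w))
            red, _, _ = map_to_tokens(red)
        else:
            if n % self.sr_ratio:
                raise ValueError(f"sequence length {n} not divisible by R={self.sr_ratio}")
            red = self.sr(x.reshape(b, n // self.sr_ratio, c * self.sr_ratio))
        return self.sr_norm(red)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        b, n, c = x.shape
        nh, dh = self.num_heads, self.head_dim
        q = self.q(x).reshape(b, n, nh, dh).transpose(0, 2, 1, 3)
        red = self._reduce(x, h, w)
        nk = red.shape[1]
        kv = self.kv(red).reshape(b, nk, 2, nh, dh).transpose(2, 0, 3, 1, 4)
        k = F.narrow(kv, 0, 0, 1).reshape(b, nh, nk, dh)
        v = F.narrow(kv, 0, 1, 1).reshape(b, nh, nk, dh)
        scores = F.matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = F.softmax(scores, axis=-1)
        attn = self.attn_drop(attn)
        out = F.matmul(attn, v).transpose(0, 2, 1, 3).reshape(b, n, c)
        return self.proj_drop(self.proj(out))

    def attention_weights(self, x: Tensor, h: int, w: int) -> np.ndarray:
        """Attention matrix (B, heads, N, N_reduced) for inspection/tests."""
        b, n, c = x.shape
        nh, dh = self.num_heads, self.head_dim
        with nn.no_grad():
            q = self.q(x).reshape(b, n, nh, dh).transpose(0, 2, 1, 3)
            red = self._reduce(x, h, w)
            nk = red.shape[1]
            kv = self.kv(red).reshape(b, nk, 2, nh, dh).transpose(2, 0, 3, 1, 4)
            k = F.narrow(kv, 0, 0, 1).reshape(b, nh, nk, dh)
            scores = F.matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
            return F.softmax(scores, axis=-1).data


class MixFFN(nn.Module):
    """FFN with an embedded 3x3 depthwise convolution as implicit positional encoding."""

    def __init__(self, cfg: StageConfig, rng: np.random.Generator,
                 dropout: float = 0.0, seed: int = 0):
        super().__init__()
        c = cfg.embed_dim
        hidden = c * cfg.mlp_ratio
        self.fc1 = nn.Linear(c, hidden, rng)
        self.dwconv = nn.Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.fc2 = nn.Linear(hidden, c, rng)
        self.drop = nn.Dropout(dropout, seed)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        y = self.fc1(x)
        y = map_to_tokens(self.dwconv(tokens_to_map(y, h, w)))[0]
        y = F.gelu(y)
        y = self.drop(y)
        y = self.fc2(y)
        return self.drop(y)


class TransformerBlock(nn.Module):
    """Pre-norm residual block: x + ESA(LN(x)); x + MixFFN(LN(x))."""

    def __init__(self, cfg: StageConfig, rng: np.random.Generator,
                 dropout: float = 0.0, sr_mode: str = "spatial", seed: int = 0):
        super().__init__()
        self.norm1 = nn.LayerNorm(cfg.embed_dim)
        self.attn = EfficientSelfAttention(cfg, rng, dropout, sr_mode, seed)
        self.norm2 = nn.LayerNorm(cfg.embed_dim)
        self.ffn = MixFFN(cfg, rng, dropout, seed + 2)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        x = x + self.attn(self.norm1(x), h, w)
        x = x + self.ffn(self.norm2(x), h, w)
        return x


class MiTEncoder(nn.Module):
    """Mix-Transformer encoder; returns the 4-level feature pyramid."""

    def __init__(self, stages=MIT_B0_STAGES, rng: np.random.Generator | None = None,
                 in_channels: int = 3, dropout: float = 0.0, sr_mode: str = "spatial"):
        super().__init__()
        if len(stages) != 4:
            raise ValueError("expected exactly 4 stage configs")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stages = tuple(stages)
        self.patch_embeds = nn.ModuleList()
        self.blocks = nn.ModuleList()
        self.norms = nn.ModuleList()
        cin = in_channels
        seed = 0
        for cfg in stages:
            self.patch_embeds.append(OverlapPatchEmbed(cin, cfg, rng))
            stage_blocks = nn.ModuleList()
            for _ in range(cfg.depth):
                stage_blocks.append(TransformerBlock(cfg, rng, dropout, sr_mode, seed))
                seed += 4
            self.blocks.append(stage_blocks)
            self.norms.append(nn.LayerNorm(cfg.embed_dim))
            cin = cfg.embed_dim

    def forward(self, x: Tensor) -> list[Tensor]:
        b, c, h, w = x.shape
        if c != 3:
            raise ValueError(f"expected 3 input channels, got {c}")
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        pyramid = []
        for embed, stage_blocks, norm in zip(self.patch_embeds, self.blocks, self.norms):
            tokens, h, w = embed(x)
            for block in stage_blocks:
                tokens = block(tokens, h, w)
            tokens = norm(tokens)
            x = tokens_to_map(tokens, h, w)
            pyramid.append(x)
        return pyramid

    @property
    def out_channels(self) -> tuple[int, ...]:
        return tuple(cfg.embed_dim for cfg in self.stages)

    def reseed_dropout(self, seed: int) -> None:
        for i, (name, mod) in enumerate(self.named_modules()):
            if isinstance(mod, nn.Dropout):
                mod.reseed(seed + i)
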