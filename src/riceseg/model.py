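"""Model assembly: configuration, decode heads, and the four ablation variants.

Variants mirror the ablation ladder:

``baseline``
    MiT-B0 encoder + the original all-MLP decode head (per-level 1x1
    projection, bilinear upsample to stride 4, concat, 1x1 fusion,
    classifier).
``p_fpn``
    the per-level projections become partial-FPN laterals with top-down
    add fusion; parameter count is identical to the baseline by design.
``p_fpn_lka``
    adds Part Large Kernel Attention on the finest fused level.
``full``
    additionally inserts the bottleneck recursive gated convolution
    after the fusion convolution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .decoder import BGnConv, PFPNFuse, PartLKA
from .encoder import MIT_B0_STAGES, MiTEncoder, StageConfig
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["VARIANTS", "ModelConfig", "MLPDecodeHead", "ImprovedDecodeHead",
           "RiceSegFormer", "build_model"]

VARIANTS = ("baseline", "p_fpn", "p_fpn_lka", "full")


@dataclass
class ModelConfig:
    """Every architectural hyperparameter, serializable to YAML."""

    variant: str = "full"
    num_classes: int = 4
    input_size: int = 512
    # encoder (MiT-B0 defaults)
    embed_dims: tuple = (32, 64, 160, 256)
    depths: tuple = (2, 2, 2, 2)
    num_heads: tuple = (1, 2, 5, 8)
    sr_ratios: tuple = (8, 4, 2, 1)
    mlp_ratios: tuple = (4, 4, 4, 4)
    patch_sizes: tuple = (7, 3, 3, 3)
    patch_strides: tuple = (4, 2, 2, 2)
    sr_mode: str = "spatial"
    dropout: float = 0.1
    # decoder
    decoder_dim: int = 256
    lka_dw_kernel: int = 5
    lka_dilated_kernel: int = 7
    lka_dilation: int = 3
    lka_compose_dilated: bool = True
    lka_levels: tuple = (0,)  # fused-pyramid levels that get Part-LKA (0 = finest)
    gn_bottleneck: int = 192
    gn_order: int = 3
    gn_kernel: int = 3
    # profiling convention (see riceseg.profile)
    flops_per_mac: int = 2
    count_attention_macs: bool = False
    profile_input_size: int = 256
    init_seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name in ("embed_dims", "depths", "num_heads", "sr_ratios",
                     "mlp_ratios", "patch_sizes", "patch_strides", "lka_levels"):
            setattr(self, name, tuple(getattr(self, name)))

    # -- encoder stages -------------------------------------------------------
    def stage_configs(self) -> tuple[StageConfig, ...]:
        return tuple(
            StageConfig(p, s, c, d, h, r, m)
            for p, s, c, d, h, r, m in zip(
                self.patch_sizes, self.patch_strides, self.embed_dims,
                self.depths, self.num_heads, self.sr_ratios, self.mlp_ratios,
            )
        )

    # -- serialization --------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class MLPDecodeHead(nn.Module):
    """Original all-MLP decode head (the baseline decoder)."""

    def __init__(self, in_channels, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.decoder_dim
        self.projections = nn.ModuleList([nn.Conv2d(c, d, 1, rng) for c in in_channels])
        self.fuse = nn.Conv2d(len(in_channels) * d, d, 1, rng)
        self.drop = nn.Dropout(cfg.dropout, cfg.init_seed + 97)
        self.classifier = nn.Conv2d(d, cfg.num_classes, 1, rng)

    def forward(self, pyramid: list[Tensor]) -> Tensor:
        h, w = pyramid[0].shape[-2:]
        maps = [
            F.resize_bilinear(proj(x), h, w)
            for proj, x in zip(self.projections, pyramid)
        ]
        y = F.relu(self.fuse(F.concat(maps, axis=1)))
        y = self.drop(y)
        return self.classifier(y)


class ImprovedDecodeHead(nn.Module):
    """Partial-FPN fusion + Part-LKA + B-gnConv decode head."""

    def __init__(self, in_channels, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.decoder_dim
        self.fpn = PFPNFuse(in_channels, d, rng)
        self.lka_levels = tuple(cfg.lka_levels) if cfg.variant in ("p_fpn_lka", "full") else ()
        self.lka = nn.ModuleList([
            PartLKA(d, rng, cfg.lka_dw_kernel, cfg.lka_dilated_kernel,
                    cfg.lka_dilation, cfg.lka_compose_dilated)
            for _ in self.lka_levels
        ])
        self.fuse = nn.Conv2d(len(in_channels) * d, d, 1, rng)
        if cfg.variant == "full":
            self.bgn = BGnConv(d, rng, cfg.gn_bottleneck, cfg.gn_order, cfg.gn_kernel)
        else:
            self.bgn = None
        self.drop = nn.Dropout(cfg.dropout, cfg.init_seed + 97)
        self.classifier = nn.Conv2d(d, cfg.num_classes, 1, rng)

    def forward(self, pyramid: list[Tensor]) -> Tensor:
        fused = self.fpn(pyramid)
        for level, lka in zip(self.lka_levels, self.lka):
            fused[level] = lka(fused[level])
        h, w = fused[0].shape[-2:]
        maps = [F.resize_bilinear(x, h, w) for x in fused]
        y = F.relu(self.fuse(F.concat(maps, axis=1)))
        if self.bgn is not None:
            y = self.bgn(y)
        y = self.drop(y)
        return self.classifier(y)


class RiceSegFormer(nn.Module):
    """Encoder + decode head; maps an image batch to per-pixel class logits."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        self.encoder = MiTEncoder(cfg.stage_configs(), rng,
                                  dropout=cfg.dropout, sr_mode=cfg.sr_mode)
        chans = self.encoder.out_channels
        if cfg.variant == "baseline":
            self.head = MLPDecodeHead(chans, cfg, rng)
        else:
            self.head = ImprovedDecodeHead(chans, cfg, rng)

    def forward(self, x: Tensor, upsample_to_input: bool = True) -> Tensor:
        h, w = x.shape[-2:]
        logits = self.head(self.encoder(x))
        if upsample_to_input:
            logits = F.resize_bilinear(logits, h, w)
        return logits

    def predict(self, x) -> np.ndarray:
        """Class-index map (B, H, W) for an image batch (no gradients)."""
        with nn.no_grad():
            logits = self.forward(nn.as_tensor(np.asarray(x, dtype=np.float32)))
        return np.argmax(logits.data, axis=1)

    def reseed_dropout(self, seed: int) -> None:
        for i, (_, mod) in enumerate(self.named_modules()):
            if isinstance(mod, nn.Dropout):
                mod.reseed(seed + 1000 * i)


def build_model(cfg: ModelConfig | dict | None = None, **overrides) -> RiceSegFormer:
    if cfg is None:
        cfg = ModelConfig(**overrides)
    elif isinstance(cfg, dict):
        cfg = ModelConfig(**{**cfg, **overrides})
    elif overrides:
        cfg = ModelConfig(**{**cfg.to_dict(), **overrides})
    return RiceSegFormer(cfg)
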