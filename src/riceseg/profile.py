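"""Parameter and FLOP accounting for the ablation ladder.

Parameters are counted exactly (every trainable scalar).  Compute is
measured by tracing one forward pass and tallying multiply-accumulate
(MAC) operations per bucket; the reported FLOP figure then follows the
declared convention:

``flops = flops_per_mac * (conv + linear [+ attention])``

The default convention — ``flops_per_mac=2``, attention products
excluded, profiling input 256x256 — mirrors the widely used module-hook
profiling scripts (thop-style hooks on convolution/projection layers,
doubled to FLOPs) and reproduces the published complexity figures for
this architecture family.  Both switches and the input size live in
:class:`~riceseg.model.ModelConfig`, so any other convention (e.g. every
MAC counted once at 512x512, attention included) is one flag away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .model import RiceSegFormer, build_model
from .nn import functional as F

__all__ = ["count_params", "param_breakdown", "count_macs", "count_flops",
           "ProfileReport", "profile_model", "profile_variant"]


def count_params(model: nn.Module) -> int:
    """Exact number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def param_breakdown(model: nn.Module, depth: int = 2) -> dict[str, int]:
    """Per-block parameter counts; blocks are name prefixes up to ``depth``."""
    out: dict[str, int] = {}
    for name, p in model.named_parameters():
        key = ".".join(name.split(".")[:depth])
        out[key] = out.get(key, 0) + int(p.data.size)
    return out


def count_macs(model: RiceSegFormer, input_size: int | None = None) -> dict[str, int]:
    """Trace one forward pass of a single image; MACs per bucket."""
    size = input_size or model.cfg.profile_input_size
    was_training = model.training
    model.eval()
    x = nn.Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    with nn.no_grad(), F.mac_counting() as counter:
        model(x)
    model.train(was_training)
    return dict(counter.macs)


def count_flops(model: RiceSegFormer, input_size: int | None = None,
                flops_per_mac: int | None = None,
                include_attention: bool | None = None) -> int:
    cfg = model.cfg
    per_mac = cfg.flops_per_mac if flops_per_mac is None else flops_per_mac
    with_attn = cfg.count_attention_macs if include_attention is None else include_attention
    macs = count_macs(model, input_size)
    total = macs["conv"] + macs["linear"] + (macs["attention"] if with_attn else 0)
    return per_mac * total


@dataclass
class ProfileReport:
    variant: str
    params: int
    flops: int
    input_size: int
    flops_per_mac: int
    attention_counted: bool
    macs: dict
    params_by_block: dict

    @property
    def params_m(self) -> float:
        return round(self.params / 1e6, 2)

    @property
    def flops_g(self) -> float:
        return round(self.flops / 1e9, 2)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params,
            "params_M": self.params_m,
            "flops": self.flops,
            "flops_G": self.flops_g,
            "input_size": self.input_size,
            "flops_per_mac": self.flops_per_mac,
            "attention_counted": self.attention_counted,
            "macs_by_bucket": self.macs,
            "params_by_block": self.params_by_block,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def table(self) -> str:
        lines = [
            f"variant            {self.variant}",
            f"params             {self.params:,}  ({self.params_m:.2f} M)",
            f"flops @{self.input_size}x{self.input_size}    {self.flops:,}  ({self.flops_g:.2f} G)"
            f"  [{self.flops_per_mac} flop/MAC, attention {'in' if self.attention_counted else 'ex'}cluded]",
            "-- params by block --",
        ]
        for k, v in sorted(self.params_by_block.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {k:30s} {v:>12,}")
        total = sum(self.params_by_block.values())
        lines.append(f"  {'total':30s} {total:>12,}")
        return "\n".join(lines)


def profile_model(model: RiceSegFormer, input_size: int | None = None) -> ProfileReport:
    cfg = model.cfg
    size = input_size or cfg.profile_input_size
    breakdown = param_breakdown(model)
    params = count_params(model)
    assert sum(breakdown.values()) == params  # breakdown must sum exactly
    return ProfileReport(
        variant=cfg.variant,
        params=params,
        flops=count_flops(model, size),
        input_size=size,
        flops_per_mac=cfg.flops_per_mac,
        attention_counted=cfg.count_attention_macs,
        macs=count_macs(model, size),
        params_by_block=breakdown,
    )


def profile_variant(variant: str, input_size: int | None = None, **overrides) -> ProfileReport:
    model = build_model(variant=variant, **overrides)
    return profile_model(model, input_size)
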