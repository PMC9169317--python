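"""Decoder fusion and bottleneck context modules.

Multi-scale feature fusion (MFF) replaces the plain U-Net skip connection.
For a coarse decoder feature x_deep and its matching encoder skip x_skip
(twice the spatial size):

    MFF = AV(DNL(x_deep)) ⊙ x_skip  +  UP(x_deep)

where AV is a channel-attention vector — global average pool, L2
normalisation, 1x1 convolution, optional sigmoid — broadcast-multiplied
(⊙) over the skip channels, and UP is 2x upsampling (bilinear by default)
followed by a 1x1 projection that aligns channel counts.

Residual SE pyramid pooling (RSEP) is an ASPP-style bottleneck: four
parallel branches of 3x3 atrous convolution (dilations 1, 6, 12, 12 by
default) each followed by squeeze-and-excitation, a 1x1 convolution and
ReLU; the branch outputs are concatenated with the original features and
fused back to the input width by a final 1x1 convolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import DNLBlock, SEBlock, fit_reduction
from .nn import Tensor, concat, no_grad
from .nn import functional as F

__all__ = ["MFFConfig", "RSEPConfig", "ChannelAttention", "MFFBlock",
           "RSEPBlock", "channel_attention_vector", "mff_fuse", "rsep_apply",
           "effective_kernel"]

_L2_EPS = 1e-12   # zero-GAP vectors normalise to zero


@dataclass(frozen=True)
class MFFConfig:
    """Fusion options: how x_deep is upsampled and how AV is bounded."""
    upsample_mode: str = "bilinear"      # bilinear | nearest | transposed_conv
    gate_activation: str = "sigmoid"     # sigmoid | none

    def __post_init__(self):
        if self.upsample_mode not in ("bilinear", "nearest", "transposed_conv"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.gate_activation not in ("sigmoid", "none"):
            raise ValueError(f"unknown gate_activation {self.gate_activation!r}")


@dataclass(frozen=True)
class RSEPConfig:
    """Pyramid-pooling options.

    The default dilation list (1, 6, 12, 12) matches the published design;
    an alternative (1, 6, 12, 18) preset is provided for users who prefer
    strictly increasing scales.
    """
    dilations: tuple[int, ...] = (1, 6, 12, 12)
    branch_channels: int | None = None   # default: C // 4 (>=1)
    se_reduction: int = 16
    padding_warn_fraction: float = 1.0   # warn if dilation > frac * min(H, W)

    ALT_DILATIONS = (1, 6, 12, 18)


def effective_kernel(kernel: int, dilation: int) -> int:
    """Effective receptive size of a dilated kernel: k + (k-1)(d-1)."""
    return kernel + (kernel - 1) * (dilation - 1)


class ChannelAttention(nn.Module):
    """AV = gate(Conv1x1(L2Normalize(GAP(x)))), a length-C_out vector."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None,
                 gate_activation: str = "sigmoid", bias: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc = nn.Linear(in_channels, out_channels, rng, bias=bias)
        self.gate_activation = gate_activation

    def forward(self, x: Tensor) -> Tensor:
        gap = x.mean(axis=(2, 3))                        # (N, C_in)
        norm = ((gap * gap).sum(axis=1, keepdims=True) + _L2_EPS) ** 0.5
        av = self.fc(gap / norm)                         # (N, C_out)
        if self.gate_activation == "sigmoid":
            av = av.sigmoid()
        return av


class MFFBlock(nn.Module):
    """One decoder fusion stage: DNL on the deep path, AV-gated skip, add UP."""

    def __init__(self, deep_channels: int, skip_channels: int,
                 cfg: MFFConfig | None = None, dnl: DNLBlock | None = None,
                 rng: np.random.Generator | None = None, dnl_kwargs=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg if cfg is not None else MFFConfig()
        self.deep_channels = deep_channels
        self.skip_channels = skip_channels
        self.dnl = dnl if dnl is not None else DNLBlock(
            deep_channels, rng=rng, **(dnl_kwargs or {}))
        self.av = ChannelAttention(deep_channels, skip_channels, rng=rng,
                                   gate_activation=self.cfg.gate_activation)
        if self.cfg.upsample_mode == "transposed_conv":
            self.up = nn.ConvTranspose2d2x(deep_channels, skip_channels, rng)
            self.proj = nn.Identity()
        else:
            self.up = None
            self.proj = nn.Conv2d(deep_channels, skip_channels, 1, rng)

    def _upsample(self, x: Tensor) -> Tensor:
        if self.cfg.upsample_mode == "bilinear":
            return self.proj(F.upsample_bilinear_2x(x))
        if self.cfg.upsample_mode == "nearest":
            return self.proj(F.upsample_nearest_2x(x))
        return self.up(x)

    def forward(self, x_deep: Tensor, x_skip: Tensor) -> Tensor:
        nd, cd, hd, wd = x_deep.shape
        ns, cs, hs, ws = x_skip.shape
        if (2 * hd, 2 * wd) != (hs, ws):
            raise ValueError(
                f"MFF expects the skip map at twice the deep resolution: "
                f"deep {tuple(x_deep.shape)} vs skip {tuple(x_skip.shape)}")
        if cd != self.deep_channels or cs != self.skip_channels:
            raise ValueError(
                f"MFF built for deep C={self.deep_channels}, skip "
                f"C={self.skip_channels}; got {cd} and {cs}")
        d = self.dnl(x_deep)
        av = self.av(d)                                   # (N, C_skip)
        mu = x_skip * av.reshape(ns, cs, 1, 1)
        return mu + self._upsample(x_deep)


class RSEPBlock(nn.Module):
    """Residual squeeze-and-excitation pyramid pooling bottleneck."""

    def __init__(self, channels: int, cfg: RSEPConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg if cfg is not None else RSEPConfig()
        self.channels = channels
        bc = self.cfg.branch_channels
        bc = bc if bc is not None else max(channels // 4, 1)
        self.branch_channels = bc
        se_r = fit_reduction(bc, self.cfg.se_reduction)
        self.branches = []
        for i, d in enumerate(self.cfg.dilations):
            branch = nn.Sequential(
                nn.Conv2d(channels, bc, 3, rng, padding=d, dilation=d),
                SEBlock(bc, se_r, rng=rng),
                nn.Conv2d(bc, bc, 1, rng),
                nn.ReLU(),
            )
            self.branches.append(branch)
            self._modules[f"branch{i}"] = branch
        self.fuse = nn.Conv2d(channels + len(self.branches) * bc,
                              channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"RSEP built for {self.channels} channels, "
                             f"input has {c}")
        cap = self.cfg.padding_warn_fraction * min(h, w)
        for d in self.cfg.dilations:
            if d > cap:
                warnings.warn(
                    f"RSEP dilation {d} pads beyond {cap:.0f} pixels for a "
                    f"{h}x{w} map; the branch mostly sees zero padding",
                    RuntimeWarning, stacklevel=2)
        outs = [x] + [branch(x) for branch in self.branches]
        return self.fuse(concat(outs, axis=1))


# --------------------------------------------------------------------------
# Functional wrappers over plain C x H x W arrays
# --------------------------------------------------------------------------

def channel_attention_vector(x: np.ndarray, block: ChannelAttention) -> np.ndarray:
    """Length-C attention vector of a C x H x W map (GAP -> L2 -> 1x1 -> gate)."""
    x = np.asarray(x, dtype=np.float64)
    block.eval()
    with no_grad():
        av = block(Tensor(x[None]))
    return av.data[0]


def mff_fuse(x_deep: np.ndarray, x_skip: np.ndarray,
             block: MFFBlock) -> np.ndarray:
    """Fuse a deep decoder map with its skip map; output matches x_skip."""
    block.eval()
    with no_grad():
        out = block(Tensor(np.asarray(x_deep, dtype=np.float64)[None]),
                    Tensor(np.asarray(x_skip, dtype=np.float64)[None]))
    return out.data[0]


def rsep_apply(x: np.ndarray, block: RSEPBlock) -> np.ndarray:
    """Apply the RSEP bottleneck to a C x H x W map (shape preserved)."""
    block.eval()
    with no_grad():
        out = block(Tensor(np.asarray(x, dtype=np.float64)[None]))
    return out.data[0]
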