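"""Attention blocks: squeeze-and-excitation, non-local, and deformed non-local.

The standard non-local (NL) block forms an (HW)x(HW) positional-similarity
matrix

    y_i = (1 / C(x)) * sum_j f(x_i, x_j) g(x_j),

with f either the embedded-Gaussian similarity exp(theta(x_i)^T phi(x_j))
(normalised by softmax over j) or the plain dot product (normalised by
N = H*W).  Its f*g product costs O(C * H^2 * W^2) multiply-accumulates.

The deformed non-local (DNL) block transposes the similarity: instead of
position-against-position it compares channel-against-channel, producing a
C̄ x C̄ attention matrix, so the f*g product drops to O(C̄^2 * H * W) — a
factor HW/C̄ fewer MACs.  The attended map is pooled into a channel
descriptor, squeezed through a bottleneck, and the resulting channel weights
gate a 1x1-convolved copy of the input; an SE tail re-calibrates channels
and a residual connection closes the block:

    y1 = softmax(theta(x) phi(x)^T) g(x)          # C̄ x HW
    y2 = pool(x) y1^T                              # 1 x C̄ descriptor
    y3 = relu(W_reduce y2);  y4 = gate(W_expand y3)  # C-vector
    out = x + SE(y4 ⊙ W_out(x))

All blocks are deterministic pure functions of (input, weights); the
functional wrappers (`se_apply`, `nl_apply`, `dnl_apply`, ...) accept plain
``C x H x W`` numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from . import nn
from .nn import Tensor, no_grad

__all__ = [
    "SEBlock", "NonLocalBlock", "DNLBlock", "OpCountReport",
    "se_apply", "nl_apply", "nl_attention", "dnl_apply", "dnl_attention",
    "fg_product_op_counts", "fit_reduction",
]


def fit_reduction(channels: int, r: int) -> int:
    """Largest divisor of `channels` that is <= r (so C/r stays integral)."""
    if r < 1:
        raise ValueError("reduction ratio must be >= 1")
    r = min(r, channels)
    while channels % r:
        r -= 1
    return r


def _check_feature_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected a C x H x W feature map, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pool per channel.  Excite: FC bottleneck
    C -> C/r -> C with ReLU then sigmoid.  The input is scaled channel-wise
    by the resulting gate in (0, 1).
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"SE reduction {reduction} does not divide {channels} channels")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.reduction = reduction
        self.fc1 = nn.Linear(channels, channels // reduction, rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        if c != self.channels:
            raise ValueError(f"SE block built for {self.channels} channels, "
                             f"input has {c}")
        s = x.mean(axis=(2, 3))                      # (N, C)
        gate = self.fc2(self.fc1(s).relu()).sigmoid()  # (N, C) in (0,1)
        return x * gate.reshape(n, c, 1, 1)


class NonLocalBlock(nn.Module):
    """Standard non-local block with positional (HW x HW) attention.

    `similarity` is ``"embedded_gaussian"`` (softmax-normalised) or
    ``"dot_product"`` (normalised by N = H*W).  The output carries the
    residual connection z = W_z y + x.
    """

    SIMILARITIES = ("embedded_gaussian", "dot_product")

    def __init__(self, channels: int, inner_channels: int | None = None,
                 similarity: str = "embedded_gaussian",
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        if similarity not in self.SIMILARITIES:
            raise ValueError(f"unknown similarity form {similarity!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        cbar = inner_channels if inner_channels is not None else channels
        self.channels = channels
        self.inner_channels = cbar
        self.similarity = similarity
        self.theta = nn.Conv2d(channels, cbar, 1, rng, bias=bias)
        self.phi = nn.Conv2d(channels, cbar, 1, rng, bias=bias)
        self.g = nn.Conv2d(channels, cbar, 1, rng, bias=bias)
        self.wz = nn.Conv2d(cbar, channels, 1, rng, bias=bias)

    def attention(self, x: Tensor) -> Tensor:
        """(N, HW, HW) positional attention; rows are normalised."""
        n, c, h, w = x.shape
        t = self.theta(x).reshape(n, self.inner_channels, h * w)
        p = self.phi(x).reshape(n, self.inner_channels, h * w)
        logits = t.swapaxes(1, 2) @ p                    # (N, HW, HW)
        if self.similarity == "embedded_gaussian":
            return logits.softmax(axis=-1)
        return logits * (1.0 / (h * w))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"NL block built for {self.channels} channels, "
                             f"input has {c}")
        attn = self.attention(x)                          # (N, HW, HW)
        gflat = self.g(x).reshape(n, self.inner_channels, h * w)
        y = gflat @ attn.swapaxes(1, 2)                   # y_i = sum_j a_ij g_j
        y = y.reshape(n, self.inner_channels, h, w)
        return self.wz(y) + x


class DNLBlock(nn.Module):
    """Deformed non-local block: channel-similarity attention + SE tail.

    Parameters
    ----------
    channels : input/output channel count C.
    inner_channels : C̄, width of the theta/phi/g embeddings (default C).
    rate : bottleneck reduction of the C̄-wide descriptor (must divide C̄).
    se_reduction : reduction ratio of the SE tail.
    gate : ``"sigmoid"`` bounds the y4 channel weights in (0,1);
        ``"none"`` leaves them unbounded.
    """

    def __init__(self, channels: int, inner_channels: int | None = None,
                 rate: int = 4, se_reduction: int = 16, gate: str = "sigmoid",
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        cbar = inner_channels if inner_channels is not None else channels
        if rate < 1 or cbar % rate:
            raise ValueError(
                f"rate {rate} must be a positive divisor of the descriptor "
                f"width {cbar}")
        if gate not in ("sigmoid", "none"):
            raise ValueError(f"unknown gate {gate!r}")
        self.channels = channels
        self.inner_channels = cbar
        self.rate = rate
        self.gate = gate
        self.theta = nn.Conv2d(channels, cbar, 1, rng, bias=bias)
        self.phi = nn.Conv2d(channels, cbar, 1, rng, bias=bias)
        self.g = nn.Conv2d(channels, cbar, 1, rng, bias=bias)
        self.pool = nn.Conv2d(channels, 1, 1, rng, bias=bias)
        self.reduce = nn.Linear(cbar, cbar // rate, rng)
        self.expand = nn.Linear(cbar // rate, channels, rng)
        self.out_conv = nn.Conv2d(channels, channels, 1, rng, bias=bias)
        self.se_tail = SEBlock(channels, fit_reduction(channels, se_reduction),
                               rng=rng)

    def attention(self, x: Tensor) -> Tensor:
        """(N, C̄, C̄) channel attention; each row is a softmax distribution."""
        n, c, h, w = x.shape
        t = self.theta(x).reshape(n, self.inner_channels, h * w)
        p = self.phi(x).reshape(n, self.inner_channels, h * w)
        logits = t @ p.swapaxes(1, 2)                    # (N, C̄, C̄)
        return logits.softmax(axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"DNL block built for {self.channels} channels, "
                             f"input has {c}")
        attn = self.attention(x)                          # (N, C̄, C̄)
        gflat = self.g(x).reshape(n, self.inner_channels, h * w)
        y1 = attn @ gflat                                 # (N, C̄, HW)
        pooled = self.pool(x).reshape(n, 1, h * w)        # (N, 1, HW)
        y2 = (pooled @ y1.swapaxes(1, 2)).reshape(n, self.inner_channels)
        y3 = self.reduce(y2).relu()
        y4 = self.expand(y3)                              # (N, C)
        if self.gate == "sigmoid":
            y4 = y4.sigmoid()
        y = self.out_conv(x) * y4.reshape(n, c, 1, 1)
        return self.se_tail(y) + x


# --------------------------------------------------------------------------
# Functional wrappers over plain C x H x W arrays
# --------------------------------------------------------------------------

def _apply_block(block: nn.Module, x: np.ndarray) -> np.ndarray:
    x = _check_feature_map(x)
    block.eval()
    with no_grad():
        out = block(Tensor(x[None]))
    return out.data[0]


def se_apply(x: np.ndarray, block: SEBlock) -> np.ndarray:
    """Apply an SE gate to a C x H x W map; output has the same shape."""
    return _apply_block(block, x)


def nl_apply(x: np.ndarray, block: NonLocalBlock) -> np.ndarray:
    """Apply a standard non-local block (with residual) to a C x H x W map."""
    return _apply_block(block, x)


def nl_attention(x: np.ndarray, block: NonLocalBlock) -> np.ndarray:
    """The (HW) x (HW) positional attention matrix for input `x`."""
    x = _check_feature_map(x)
    block.eval()
    with no_grad():
        attn = block.attention(Tensor(x[None]))
    return attn.data[0]


def dnl_apply(x: np.ndarray, block: DNLBlock) -> np.ndarray:
    """Apply a deformed non-local block (with residual) to a C x H x W map."""
    return _apply_block(block, x)


def dnl_attention(x: np.ndarray, block: DNLBlock) -> np.ndarray:
    """The C̄ x C̄ channel attention matrix for input `x`."""
    x = _check_feature_map(x)
    block.eval()
    with no_grad():
        attn = block.attention(Tensor(x[None]))
    return attn.data[0]


# --------------------------------------------------------------------------
# Analytic complexity accounting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpCountReport:
    """Multiply-accumulate counts of the f*g attention product.

    ``ratio`` is exact rational arithmetic: nl/dnl == HW / C̄ whenever both
    blocks share C̄, H, W.
    """

    nl_fg_macs: int
    dnl_fg_macs: int
    ratio: Fraction


def fg_product_op_counts(cbar: int, height: int, width: int) -> OpCountReport:
    """MAC counts of attention_matrix @ g for NL vs DNL at equal C̄, H, W.

    NL multiplies an (HW x HW) attention with g (C̄ x HW): C̄ * (HW)^2 MACs.
    DNL multiplies a (C̄ x C̄) attention with g (C̄ x HW): C̄^2 * HW MACs.
    """
    if cbar < 1 or height < 1 or width < 1:
        raise ValueError("all dimensions must be >= 1")
    hw = height * width
    nl = cbar * hw * hw
    dnl = hw * cbar * cbar
    return OpCountReport(nl_fg_macs=nl, dnl_fg_macs=dnl,
                         ratio=Fraction(nl, dnl))
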