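"""Spatial NN primitives (NCHW layout) with hand-written backward passes.

Convolution is computed by an im2col gather (``sliding_window_view``) and an
einsum contraction; its input gradient is the matching col2im scatter-add.
All primitives operate on :class:`~dnlseg.nn.tensor.Tensor` and record
closures for reverse-mode differentiation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d", "conv_transpose2d_2x", "max_pool2d_2x",
    "upsample_nearest_2x", "upsample_bilinear_2x",
]


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int, dilation: int) -> np.ndarray:
    """Return windows of shape (N, C, Ho, Wo, kh, kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    win = sliding_window_view(x, (eh, ew), axis=(2, 3))
    return win[..., ::dilation, ::dilation]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2D convolution (cross-correlation), stride 1, NCHW / OIHW layout."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    cols = _im2col(x.data, kh, kw, padding, dilation)
    out_data = np.einsum("nchwij,ocij->nohw", cols, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
    ho, wo = out_data.shape[2], out_data.shape[3]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        grads = []
        # input gradient: col2im scatter-add
        hp, wp = h + 2 * padding, w + 2 * padding
        gxp = np.zeros((n, c, hp, wp))
        dcols = np.einsum("nohw,ocij->nchwij", g, weight.data, optimize=True)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i * dilation:i * dilation + ho,
                    j * dilation:j * dilation + wo] += dcols[:, :, :, :, i, j]
        gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
        grads.append((x, gx))
        gw = np.einsum("nchwij,nohw->ocij", cols, g, optimize=True)
        grads.append((weight, gw))
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return grads

    return Tensor._make(out_data, parents, backward)


def conv_transpose2d_2x(x: Tensor, weight: Tensor,
                        bias: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    With kernel == stride each output pixel receives exactly one
    contribution, so the op is a channel mix followed by a pixel-shuffle.
    Weight layout: (C_in, C_out, 2, 2).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    ci, co, kh, kw = weight.data.shape
    if ci != c or (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2d_2x expects weight (C_in, C_out, 2, 2)")
    # y[n,o,2i+a,2j+b] = sum_c x[n,c,i,j] w[c,o,a,b]
    y = np.einsum("nchw,coab->nohawb", x.data, weight.data, optimize=True)
    out_data = y.reshape(n, co, 2 * h, 2 * w)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g6 = g.reshape(n, co, h, 2, w, 2)
        gx = np.einsum("nohawb,coab->nchw", g6, weight.data, optimize=True)
        gw = np.einsum("nohawb,nchw->coab", g6, x.data, optimize=True)
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return grads

    return Tensor._make(out_data, parents, backward)


def max_pool2d_2x(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d_2x needs even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    blocks = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, ho, wo, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return [(x, gx.reshape(n, c, h, w))]

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest_2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        return [(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))]

    return Tensor._make(out_data, (x,), backward)


def _bilinear_axis_weights(n_in: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source indices and interpolation weight for a 2x bilinear resize
    (half-pixel center convention, edges clamped)."""
    dst = np.arange(2 * n_in)
    src = (dst + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    t = np.clip(src - np.floor(src), 0.0, 1.0)
    t = np.where(src < 0, 0.0, t)
    t = np.where(src > n_in - 1, 0.0, t)
    return i0, i1, t


def upsample_bilinear_2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    r0, r1, rt = _bilinear_axis_weights(h)
    c0, c1, ct = _bilinear_axis_weights(w)
    rt_ = rt.reshape(1, 1, -1, 1)
    ct_ = ct.reshape(1, 1, 1, -1)

    def interp(a: np.ndarray) -> np.ndarray:
        rows = a[:, :, r0, :] * (1 - rt_) + a[:, :, r1, :] * rt_
        return rows[:, :, :, c0] * (1 - ct_) + rows[:, :, :, c1] * ct_

    out_data = interp(x.data)

    def backward(g):
        # adjoint of column interpolation
        grows = np.zeros((n, c, 2 * h, w))
        np.add.at(grows, (slice(None), slice(None), slice(None), c0),
                  g * (1 - ct_))
        np.add.at(grows, (slice(None), slice(None), slice(None), c1), g * ct_)
        gx = np.zeros((n, c, h, w))
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)),
                  grows * (1 - rt_))
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)), grows * rt_)
        return [(x, gx)]

    return Tensor._make(out_data, (x,), backward)
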