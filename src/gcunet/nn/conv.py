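"""Spatial ops (NCHW): convolution, transposed convolution, pooling, resizing.

Convolutions are lowered to matrix products via im2col; the backward pass
uses the matching col2im scatter. All ops preserve the input dtype.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Tensor, _make, as_tensor


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    n = xp.shape[0]
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    ho, wo = v.shape[2], v.shape[3]
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, -1, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols, n, c, hp, wp, kh, kw, sh, sw, ho, wo):
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += d[:, :, i, j]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, kh, kw, stride, stride)
    wmat = weight.data.reshape(o, -1)
    out = np.matmul(wmat[None], cols).reshape(n, o, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gf = g.reshape(n, o, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.einsum("nol,nkl->ok", gf, cols, optimize=True)
            weight._accumulate(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = np.matmul(wmat.T[None], gf)
            dxp = _col2im(dcols, n, c, xp.shape[2], xp.shape[3], kh, kw,
                          stride, stride, ho, wo)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return _make(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed conv; `weight` has shape (C_in, C_out, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    ci, co, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv_transpose2d channel mismatch: {c} vs {ci}")
    hp = (h - 1) * stride + kh
    wp = (w - 1) * stride + kw
    hout, wout = hp - 2 * padding, wp - 2 * padding
    wmat = weight.data.reshape(ci, -1)  # (C_in, C_out*kh*kw)
    cols = np.matmul(wmat.T[None], x.data.reshape(n, c, h * w))
    outp = _col2im(cols, n, co, hp, wp, kh, kw, stride, stride, h, w)
    out = outp[:, :, padding : padding + hout, padding : padding + wout]
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        gcols, _, _ = _im2col(gp, kh, kw, stride, stride)  # (N, C_out*kh*kw, h*w)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.einsum("nil,nkl->ik", x.data.reshape(n, c, h * w), gcols,
                           optimize=True)
            weight._accumulate(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dx = np.matmul(wmat[None], gcols).reshape(n, c, h, w)
            x._accumulate(dx)

    return _make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling, floor mode (trailing remainder dropped)."""
    x = as_tensor(x)
    stride = kernel if stride is None else stride
    n, c, h, w = x.data.shape
    if h + 2 * padding < kernel or w + 2 * padding < kernel:
        raise ValueError(
            f"max_pool2d: input {h}x{w} smaller than pool kernel {kernel}")
    neg = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else np.iinfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    hp, wp = xp.shape[2], xp.shape[3]
    v = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = v.shape[2], v.shape[3]
    flat = v.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        oh, ow = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oh[None, None] * stride + idx // kernel
        cols_ = ow[None, None] * stride + idx % kernel
        nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        base = (nn * c + cc)[..., None, None] * (hp * wp)
        flat_idx = base + rows * wp + cols_
        dxp = np.zeros(n * c * hp * wp, dtype=g.dtype)
        np.add.at(dxp, flat_idx.ravel(), g.ravel())
        dxp = dxp.reshape(n, c, hp, wp)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    return _make(np.ascontiguousarray(out), (x,), backward)


def avg_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping average pooling (stride = kernel, floor mode)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    ho, wo = h // kernel, w // kernel
    v = x.data[:, :, : ho * kernel, : wo * kernel].reshape(n, c, ho, kernel, wo, kernel)
    out = v.mean(axis=(3, 5))

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        gexp = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3) / (kernel * kernel)
        dx[:, :, : ho * kernel, : wo * kernel] = gexp
        x._accumulate(dx)

    return _make(out, (x,), backward)


def _bin_edges(size: int, bins: int):
    lo = (np.arange(bins) * size) // bins
    hi = -(-(np.arange(1, bins + 1) * size) // bins)  # ceil division
    return lo, hi


def adaptive_avg_pool2d(x: Tensor, out_size: int) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h < out_size or w < out_size:
        raise ValueError(
            f"adaptive_avg_pool2d: input {h}x{w} smaller than output grid {out_size}")
    hlo, hhi = _bin_edges(h, out_size)
    wlo, whi = _bin_edges(w, out_size)
    out = np.empty((n, c, out_size, out_size), dtype=x.data.dtype)
    for i in range(out_size):
        for j in range(out_size):
            out[:, :, i, j] = x.data[:, :, hlo[i]:hhi[i], wlo[j]:whi[j]].mean(axis=(2, 3))

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for i in range(out_size):
            for j in range(out_size):
                area = (hhi[i] - hlo[i]) * (whi[j] - wlo[j])
                dx[:, :, hlo[i]:hhi[i], wlo[j]:whi[j]] += g[:, :, i, j, None, None] / area
        x._accumulate(dx)

    return _make(out, (x,), backward)


def _interp_matrix(out_len: int, in_len: int, mode: str) -> np.ndarray:
    m = np.zeros((out_len, in_len))
    o = np.arange(out_len)
    if mode == "nearest":
        idx = np.minimum((o * in_len) // out_len, in_len - 1)
        m[o, idx] = 1.0
    elif mode == "bilinear":
        c = np.clip((o + 0.5) * in_len / out_len - 0.5, 0, in_len - 1)
        i0 = np.floor(c).astype(int)
        i1 = np.minimum(i0 + 1, in_len - 1)
        frac = c - i0
        np.add.at(m, (o, i0), 1.0 - frac)
        np.add.at(m, (o, i1), frac)
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return m


def upsample(x: Tensor, size: tuple[int, int], mode: str = "bilinear") -> Tensor:
    """Resize to `size` = (H_out, W_out); separable row/column interpolation."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    ho, wo = size
    mh = _interp_matrix(ho, h, mode).astype(x.data.dtype)
    mw = _interp_matrix(wo, w, mode).astype(x.data.dtype)
    tmp = np.einsum("oh,nchw->ncow", mh, x.data, optimize=True)
    out = np.einsum("pw,ncow->ncop", mw, tmp, optimize=True)

    def backward(g):
        if not x.requires_grad:
            return
        t = np.einsum("pw,ncop->ncow", mw, g, optimize=True)
        x._accumulate(np.einsum("oh,ncow->nchw", mh, t, optimize=True))

    return _make(out, (x,), backward)
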