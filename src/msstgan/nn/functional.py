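"""Convolution, resampling and padding primitives with custom gradients."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["conv2d", "bilinear_resize", "zero_upsample2x", "interp_matrix"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*kh*kw, Ho*Wo) patch matrix."""
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
    b, c, ho, wo = view.shape[:4]
    return view.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    """Scatter-add transpose of :func:`_im2col`."""
    b, c, h, w = x_shape
    x = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of NCHW input with (Cout, Cin, kh, kw) weights."""
    x, weight = as_tensor(x), as_tensor(weight)
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    w2 = weight.data.reshape(cout, -1)
    out = np.einsum("ok,bkp->bop", w2, cols, optimize=True)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1)
    out = out.reshape(x.shape[0], cout, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(g.shape[0], cout, -1)  # (B, Cout, P)
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", g2, cols, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,bop->bkp", w2, g2, optimize=True)
            gxp = _col2im(gcols, xp.shape, kh, kw, stride, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return Tensor(out, parents=parents, backward=backward)


def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-interpolation matrix for bilinear resize, half-pixel-center
    (non-aligned-corner) convention: A[i, :] holds the two source weights
    for output sample i, so `out = A @ x`."""
    A = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        A[i, lo] += 1.0 - frac
        A[i, hi] += frac
    return A


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor to (out_h, out_w)."""
    x = as_tensor(x)
    _, _, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    A = interp_matrix(out_h, h)
    B = interp_matrix(out_w, w)
    out = np.einsum("ij,bcjk,lk->bcil", A, x.data, B, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("ij,bcil,lk->bcjk", A, g, B, optimize=True))

    return Tensor(out, parents=(x,), backward=backward)


def zero_upsample2x(x: Tensor) -> Tensor:
    """Insert zeros between samples (stride-2 transposed-conv front half)."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    out = np.zeros((b, c, 2 * h, 2 * w))
    out[:, :, ::2, ::2] = x.data

    def backward(g):
        if x.requires_grad:
            x._accum(g[:, :, ::2, ::2])

    return Tensor(out, parents=(x,), backward=backward)
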