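"""Functional ops on :class:`~ringseg.nn.autodiff.Tensor` values.

Convolutions support circular padding along the *width* axis, which is
the angular dimension of polar images; the height axis (radial) is
always zero padded.  Strides are not implemented — spatial reduction is
done with average pooling, upsampling with (bi)linear resizing.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = ["conv2d", "avg_pool2d", "resize_linear", "resize_bilinear", "concat", "pow_"]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, dilation=(1, 1), circular=False) -> Tensor:
    """Same-size 2-D convolution (cross-correlation), stride 1.

    x: (Cin, H, W); weight: (Cout, Cin, kh, kw); bias: (Cout,).
    ``circular`` wraps the width (angular) axis; height is zero padded.
    """
    cin, H, W = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    dh, dw = dilation
    ph, pw = dh * (kh // 2), dw * (kw // 2)

    xd = x.data
    if circular and pw > 0:
        xd = np.concatenate([xd[:, :, -pw:], xd, xd[:, :, :pw]], axis=2)
    elif pw > 0:
        xd = np.pad(xd, ((0, 0), (0, 0), (pw, pw)))
    if ph > 0:
        xd = np.pad(xd, ((0, 0), (ph, ph), (0, 0)))

    span_h, span_w = dh * (kh - 1) + 1, dw * (kw - 1) + 1
    win = sliding_window_view(xd, (span_h, span_w), axis=(1, 2))
    win = win[:, :, :, ::dh, ::dw]  # (Cin, H, W, kh, kw)
    cols = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(
        H * W, cin * kh * kw
    )
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = (cols @ wmat.T).T.reshape(cout, H, W) + bias.data[:, None, None]

    def back_x(g):
        gcols = g.reshape(cout, H * W).T @ wmat  # (H*W, Cin*kh*kw)
        gcols = np.ascontiguousarray(
            gcols.reshape(H, W, cin, kh, kw).transpose(3, 4, 2, 0, 1)
        )  # (kh, kw, Cin, H, W)
        gpad = np.zeros_like(xd)
        for i in range(kh):
            for j in range(kw):
                gpad[:, i * dh : i * dh + H, j * dw : j * dw + W] += gcols[i, j]
        if ph > 0:
            gpad = gpad[:, ph : ph + H, :]
        if pw > 0:
            if circular:
                gpad[:, :, pw : 2 * pw] += gpad[:, :, W + pw :]
                gpad[:, :, W : W + pw] += gpad[:, :, :pw]
            gpad = gpad[:, :, pw : pw + W]
        return gpad.astype(np.float32)

    def back_w(g):
        return (g.reshape(cout, H * W) @ cols).reshape(weight.shape).astype(np.float32)

    def back_b(g):
        return g.sum(axis=(1, 2)).astype(np.float32)

    return Tensor(out, parents=((x, back_x), (weight, back_w), (bias, back_b)))


def avg_pool2d(x: Tensor, kh: int, kw: int) -> Tensor:
    """Non-overlapping average pooling; spatial dims must be divisible."""
    c, H, W = x.shape
    if H % kh or W % kw:
        raise ValueError(f"pool {kh}x{kw} does not divide {H}x{W}")
    out = x.data.reshape(c, H // kh, kh, W // kw, kw).mean(axis=(2, 4))

    def back(g):
        g = g[:, :, None, :, None] / (kh * kw)
        return np.broadcast_to(
            g, (c, H // kh, kh, W // kw, kw)
        ).reshape(c, H, W).astype(np.float32)

    return Tensor(out, parents=((x, back),))


def _linear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D linear-interpolation matrix (half-pixel-center mapping)."""
    if n_out == n_in:
        return np.eye(n_in, dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(np.float32)
    A = np.zeros((n_out, n_in), dtype=np.float32)
    A[np.arange(n_out), i0] += 1.0 - w1
    A[np.arange(n_out), i1] += w1
    return A


def resize_linear(x: Tensor, n_out: int, axis: int) -> Tensor:
    """Linear resize along one axis of a (C, H, W) tensor."""
    n_in = x.shape[axis]
    A = _linear_matrix(n_out, n_in)
    moved = np.moveaxis(x.data, axis, -1)
    out = np.moveaxis(moved @ A.T, -1, axis)

    def back(g):
        gm = np.moveaxis(g, axis, -1)
        return np.moveaxis(gm @ A, -1, axis).astype(np.float32)

    return Tensor(out, parents=((x, back),))


def resize_bilinear(x: Tensor, h_out: int, w_out: int) -> Tensor:
    return resize_linear(resize_linear(x, h_out, axis=1), w_out, axis=2)


def concat(tensors, axis=0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_back(i):
        def back(g):
            return np.split(g, splits, axis=axis)[i]

        return back

    return Tensor(out, parents=tuple((t, make_back(i)) for i, t in enumerate(tensors)))


def pow_(x: Tensor, p: float) -> Tensor:
    out = x.data**p

    def back(g):
        return (g * p * x.data ** (p - 1)).astype(np.float32)

    return Tensor(out, parents=((x, back),))
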