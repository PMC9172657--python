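"""Convolutional primitives (im2col based) wired into the autodiff tape.

All image tensors are NCHW float32. ``conv2d`` and ``conv_transpose2d`` share
the same im2col / col2im pair: the transposed convolution's forward pass is
the data-gradient of the ordinary convolution and vice versa, so each op's
backward reuses the other's forward machinery.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2d", "maxpool2d"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N,C,k,k,Ho,Wo) patch view (contiguous copy)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, out_hw: tuple[int, int], k: int, stride: int,
            pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c = cols.shape[:2]
    ho, wo = cols.shape[4], cols.shape[5]
    h, w = out_hw
    buf = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            buf[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                cols[:, :, i, j]
    if pad:
        buf = buf[:, :, pad:pad + h, pad:pad + w]
    return buf


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation. weight: (Cout, Cin, k, k)."""
    cout, cin, k, _ = weight.shape
    n, c, h, w = x.shape
    if c != cin:
        raise ValueError(f"conv2d expects {cin} input channels, got {c}")
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"conv2d: input {h}x{w} too small for kernel {k} stride {stride}")
    cols = _im2col(x.data, k, stride, pad)             # (N,Cin,k,k,Ho,Wo)
    cols2 = cols.reshape(n, cin * k * k, ho * wo)
    wmat = weight.data.reshape(cout, cin * k * k)
    out_data = np.einsum("oi,nij->noj", wmat, cols2,
                         optimize=True).reshape(n, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    req = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    out = Tensor(out_data, req)
    if req:
        prev = [x, weight] + ([bias] if bias is not None else [])
        out._prev = tuple(prev)

        def _bw(g):
            gm = g.reshape(n, cout, ho * wo)
            if weight.requires_grad:
                gw = np.einsum("noj,nij->oi", gm, cols2, optimize=True)
                weight._accumulate(gw.reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.einsum("oi,noj->nij", wmat, gm, optimize=True)
                gx = _col2im(gcols.reshape(n, cin, k, k, ho, wo),
                             (h, w), k, stride, pad)
                x._accumulate(gx)
        out._backward = _bw
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, pad: int = 0) -> Tensor:
    """Transposed 2-D convolution. weight: (Cin, Cout, k, k).

    Output spatial size: (H-1)*stride - 2*pad + k.
    """
    cin, cout, k, _ = weight.shape
    n, c, h, w = x.shape
    if c != cin:
        raise ValueError(f"conv_transpose2d expects {cin} channels, got {c}")
    ho = (h - 1) * stride - 2 * pad + k
    wo = (w - 1) * stride - 2 * pad + k
    if ho < 1 or wo < 1:
        raise ValueError("conv_transpose2d: output size would be empty")
    # cols[n, cout, k, k, h, w] = sum_cin w[cin,cout,k,k] * x[n,cin,h,w]
    cols = np.einsum("nihw,iokl->noklhw", x.data, weight.data, optimize=True)
    out_data = _col2im(cols, (ho, wo), k, stride, pad)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    req = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    out = Tensor(out_data, req)
    if req:
        prev = [x, weight] + ([bias] if bias is not None else [])
        out._prev = tuple(prev)

        def _bw(g):
            gcols = _im2col(g, k, stride, pad)          # (N,Cout,k,k,H,W)
            if x.requires_grad:
                gx = np.einsum("noklhw,iokl->nihw", gcols, weight.data,
                               optimize=True)
                x._accumulate(gx)
            if weight.requires_grad:
                gw = np.einsum("nihw,noklhw->iokl", x.data, gcols,
                               optimize=True)
                weight._accumulate(gw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
        out._backward = _bw
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling (H, W must be divisible by k)."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: {h}x{w} not divisible by {k}")
    ho, wo = h // k, w // k
    r = x.data.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, ho, wo, k * k)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad)
    if out.requires_grad:
        out._prev = (x,)

        def _bw(g):
            gr = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = gr.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gx.reshape(n, c, h, w))
        out._backward = _bw
    return out
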