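"""Low-level convolution kernels (forward, input-gradient, weight-gradient).

Layout is NCHW. Small problems go through an im2col buffer and a single BLAS
GEMM; when the buffer would be large (wide planes at inference) the kernels
fall back to a loop over the kernel taps, each tap a strided einsum, which
keeps memory flat.

``pad`` is always an explicit pair of pairs ``((top, bottom), (left, right))``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: im2col buffers above this many elements use the tap-loop path instead
#: (empirical crossover: the gather/copy outweighs the single GEMM above ~4M)
_COL_LIMIT = 4_000_000


def same_pad(k: int, dilation: int = 1) -> tuple[int, int]:
    """Symmetric padding that keeps the plane size under stride 1."""
    eff = dilation * (k - 1) + 1
    total = eff - 1
    return total // 2, total - total // 2


def out_size(n: int, k: int, stride: int, dilation: int, pad: tuple[int, int]) -> int:
    eff = dilation * (k - 1) + 1
    return (n + pad[0] + pad[1] - eff) // stride + 1


def _geometry(x_shape, w_shape, stride, dilation, pad):
    n, c, h, wid = x_shape
    co, ci, kh, kw = w_shape
    ho = out_size(h, kh, stride[0], dilation[0], pad[0])
    wo = out_size(wid, kw, stride[1], dilation[1], pad[1])
    return n, c, h, wid, co, kh, kw, ho, wo


def _cols(xp, kh, kw, sh, sw, dh, dw, ho, wo):
    """(N, C, Ho, Wo, kh, kw) gather view -> contiguous (N*Ho*Wo, C*kh*kw)."""
    eff_h, eff_w = dh * (kh - 1) + 1, dw * (kw - 1) + 1
    view = sliding_window_view(xp, (eff_h, eff_w), axis=(2, 3))
    view = view[:, :, ::sh, ::sw, ::dh, ::dw][:, :, :ho, :wo]
    n, c = xp.shape[0], xp.shape[1]
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)


def conv2d_fwd(x, w, b=None, stride=(1, 1), dilation=(1, 1), pad=((0, 0), (0, 0))):
    """x: (N,C,H,W); w: (Cout,Cin,kh,kw); returns (N,Cout,Ho,Wo)."""
    n, c, h, wid, co, kh, kw, ho, wo = _geometry(x.shape, w.shape, stride, dilation, pad)
    xp = np.pad(x, ((0, 0), (0, 0), pad[0], pad[1]))
    if n * ho * wo * c * kh * kw <= _COL_LIMIT:
        cols = _cols(xp, kh, kw, *stride, *dilation, ho, wo)
        out = cols @ w.reshape(co, -1).T
        out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
        out = np.ascontiguousarray(out)
    else:
        out = np.zeros((n, co, ho, wo), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i * dilation[0]: i * dilation[0] + stride[0] * ho: stride[0],
                           j * dilation[1]: j * dilation[1] + stride[1] * wo: stride[1]]
                out += np.einsum("nchw,oc->nohw", patch, w[:, :, i, j], optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    return out


def conv2d_bwd_x(dout, w, x_shape, stride=(1, 1), dilation=(1, 1), pad=((0, 0), (0, 0))):
    """Gradient w.r.t. the input (also the forward pass of a transposed conv)."""
    n, c, h, wid, co, kh, kw, ho, wo = _geometry(x_shape, w.shape, stride, dilation, pad)
    sh, sw = stride
    dh, dw = dilation
    dxp = np.zeros((n, c, h + pad[0][0] + pad[0][1], wid + pad[1][0] + pad[1][1]),
                   dtype=dout.dtype)
    if n * ho * wo * c * kh * kw <= _COL_LIMIT:
        dcols = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, co) @ w.reshape(co, -1)
        dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i * dh: i * dh + sh * ho: sh,
                    j * dw: j * dw + sw * wo: sw] += dcols[:, :, i, j]
    else:
        for i in range(kh):
            for j in range(kw):
                contrib = np.einsum("nohw,oc->nchw", dout, w[:, :, i, j], optimize=True)
                dxp[:, :, i * dh: i * dh + sh * ho: sh,
                    j * dw: j * dw + sw * wo: sw] += contrib
    return dxp[:, :, pad[0][0]: pad[0][0] + h, pad[1][0]: pad[1][0] + wid]


def conv2d_bwd_w(x, dout, w_shape, stride=(1, 1), dilation=(1, 1), pad=((0, 0), (0, 0))):
    """Gradient w.r.t. the kernel."""
    co, ci, kh, kw = w_shape
    n, c, h, wid, co, kh, kw, ho, wo = _geometry(x.shape, w_shape, stride, dilation, pad)
    xp = np.pad(x, ((0, 0), (0, 0), pad[0], pad[1]))
    if n * ho * wo * c * kh * kw <= _COL_LIMIT:
        cols = _cols(xp, kh, kw, *stride, *dilation, ho, wo)
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        return (dmat.T @ cols).reshape(w_shape)
    dw_out = np.zeros(w_shape, dtype=dout.dtype)
    sh, sw = stride
    dh, dw = dilation
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i * dh: i * dh + sh * ho: sh, j * dw: j * dw + sw * wo: sw]
            dw_out[:, :, i, j] = np.einsum("nchw,nohw->oc", patch, dout, optimize=True)
    return dw_out
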