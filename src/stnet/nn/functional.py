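"""Convolutional primitives with hand-written backward passes.

All spatial operations use NCHW layout, (row, col) coordinates with 0-based
pixel centers at integer positions, and zero padding for out-of-bounds reads.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor, _make

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "deformable_conv2d",
    "bilinear_sample_map",
    "gradient_scale",
]


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Return patch tensor of shape (N, C, kh, kw, Ho, Wo)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Ho',Wo',kh,kw
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))


def _col2im(cols: np.ndarray, H: int, W: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add patches (N, C, kh, kw, Ho, Wo) back onto an (N,C,H,W) grid."""
    N, C, kh, kw, Ho, Wo = cols.shape
    out = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += (
                cols[:, :, i, j]
            )
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Grouped 2-D convolution (cross-correlation, as is conventional).

    ``weight`` has shape (C_out, C_in/groups, kh, kw).  Output channel j of
    group i depends only on the input channels of group i, so parameter count
    is C_out * (C_in/groups) * kh * kw.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    N, C, H, W = x.data.shape
    Co, Cg, kh, kw = weight.data.shape
    if C % groups or Co % groups or Cg != C // groups:
        raise ValueError(
            f"groups={groups} must divide in/out channels ({C}, {Co}); "
            f"weight expects {Cg} channels per group"
        )
    Ho, Wo = _out_size(H, kh, stride, padding), _out_size(W, kw, stride, padding)
    cols = _im2col(x.data, kh, kw, stride, padding)
    K = (C // groups) * kh * kw
    colsg = cols.reshape(N, groups, K, Ho * Wo)
    wg = weight.data.reshape(groups, Co // groups, K)
    out_data = np.matmul(wg[None], colsg).reshape(N, Co, Ho, Wo)
    parents = (x, weight) if bias is None else (x, weight, as_tensor(bias))
    if bias is not None:
        out_data = out_data + parents[2].data.reshape(1, Co, 1, 1)
    out = _make(out_data, parents)
    if out._parents:
        def bw(g):
            gg = g.reshape(N, groups, Co // groups, Ho * Wo)
            if weight.requires_grad or weight._parents:
                dw = np.matmul(gg, colsg.transpose(0, 1, 3, 2)).sum(axis=0)
                weight._accumulate(dw.reshape(weight.data.shape))
            if x.requires_grad or x._parents:
                dcols = np.matmul(wg.transpose(0, 2, 1)[None], gg)
                dcols = dcols.reshape(N, C, kh, kw, Ho, Wo)
                x._accumulate(_col2im(dcols, H, W, stride, padding))
            if bias is not None and (parents[2].requires_grad or parents[2]._parents):
                parents[2]._accumulate(g.sum(axis=(0, 2, 3)).reshape(parents[2].data.shape))
        out._backward = bw
    return out


def conv_transpose2d(x, weight, bias=None, stride: int = 1,
                     padding: int = 0) -> Tensor:
    """Transposed convolution; ``weight`` has shape (C_in, C_out, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    N, Ci, H, W = x.data.shape
    Ci2, Co, kh, kw = weight.data.shape
    if Ci != Ci2:
        raise ValueError(f"input has {Ci} channels, weight expects {Ci2}")
    Ho = (H - 1) * stride - 2 * padding + kh
    Wo = (W - 1) * stride - 2 * padding + kw
    xm = x.data.reshape(N, Ci, H * W)
    wm = weight.data.reshape(Ci, Co * kh * kw)
    cols = np.einsum("ck,ncl->nkl", wm, xm).reshape(N, Co, kh, kw, H, W)
    out_data = _col2im(cols, Ho, Wo, stride, padding)
    parents = (x, weight) if bias is None else (x, weight, as_tensor(bias))
    if bias is not None:
        out_data = out_data + parents[2].data.reshape(1, Co, 1, 1)
    out = _make(out_data, parents)
    if out._parents:
        def bw(g):
            dcols = _im2col(g, kh, kw, stride, padding)  # N,Co,kh,kw,H,W
            dcols_flat = dcols.reshape(N, Co * kh * kw, H * W)
            if x.requires_grad or x._parents:
                dx = np.einsum("ck,nkl->ncl", wm, dcols_flat)
                x._accumulate(dx.reshape(N, Ci, H, W))
            if weight.requires_grad or weight._parents:
                dw = np.einsum("ncl,nkl->ck", xm, dcols_flat)
                weight._accumulate(dw.reshape(weight.data.shape))
            if bias is not None and (parents[2].requires_grad or parents[2]._parents):
                parents[2]._accumulate(g.sum(axis=(0, 2, 3)).reshape(parents[2].data.shape))
        out._backward = bw
    return out


def max_pool2d(x, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or kernel
    N, C, H, W = x.data.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = sliding_window_view(xd, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    N_, C_, Ho, Wo = win.shape[:4]
    flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = _make(flat.max(axis=-1), (x,))
    if out._parents:
        def bw(g):
            Hp, Wp = H + 2 * padding, W + 2 * padding
            grad = np.zeros((N, C, Hp * Wp), dtype=np.float64)
            di, dj = idx // kernel, idx % kernel
            base_i = np.arange(Ho)[:, None] * stride
            base_j = np.arange(Wo)[None, :] * stride
            rows = base_i[None, None] + di
            cols_ = base_j[None, None] + dj
            flat_idx = (rows * Wp + cols_).reshape(N, C, Ho * Wo)
            np.add.at(
                grad.reshape(N * C, Hp * Wp),
                (np.repeat(np.arange(N * C), Ho * Wo),
                 flat_idx.reshape(N * C * Ho * Wo)),
                g.reshape(N * C * Ho * Wo),
            )
            grad = grad.reshape(N, C, Hp, Wp)
            if padding:
                grad = grad[:, :, padding:-padding, padding:-padding]
            x._accumulate(grad)
        out._backward = bw
    return out


def bilinear_sample_map(x: np.ndarray, py: np.ndarray, px: np.ndarray):
    """Bilinearly sample channel-stack ``x`` (N,C,H,W) at fractional (row, col)
    positions (each of shape (N, K, L)).  Out-of-bounds reads contribute zero.

    Returns (values (N,C,K,L), cache) where the cache carries the corner
    values and interpolation weights needed by the backward pass.
    """
    N, C, H, W = x.shape
    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    wy = py - y0
    wx = px - x0
    xflat = x.reshape(N, C, H * W)
    corners = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yc, xc = y0 + dy, x0 + dx
        valid = (yc >= 0) & (yc < H) & (xc >= 0) & (xc < W)
        idx = np.clip(yc, 0, H - 1) * W + np.clip(xc, 0, W - 1)
        K, L = idx.shape[1], idx.shape[2]
        v = np.take_along_axis(
            xflat, np.broadcast_to(idx.reshape(N, 1, K * L), (N, C, K * L)), axis=2
        ).reshape(N, C, K, L)
        v *= valid[:, None]
        corners.append((v, valid, idx))
    (v00, m00, i00), (v01, m01, i01), (v10, m10, i10), (v11, m11, i11) = corners
    wy_, wx_ = wy[:, None], wx[:, None]
    val = ((1 - wy_) * (1 - wx_) * v00 + (1 - wy_) * wx_ * v01
           + wy_ * (1 - wx_) * v10 + wy_ * wx_ * v11)
    cache = (corners, wy, wx, (N, C, H, W))
    return val, cache


def _bilinear_backward(dval: np.ndarray, cache):
    """Gradients of bilinear sampling wrt the source map and the positions."""
    corners, wy, wx, (N, C, H, W) = cache
    (v00, m00, i00), (v01, m01, i01), (v10, m10, i10), (v11, m11, i11) = corners
    wy_, wx_ = wy[:, None], wx[:, None]
    weights = (
        (m00, i00, (1 - wy_) * (1 - wx_)),
        (m01, i01, (1 - wy_) * wx_),
        (m10, i10, wy_ * (1 - wx_)),
        (m11, i11, wy_ * wx_),
    )
    dx = np.zeros((N, C, H * W), dtype=np.float64)
    K, L = wy.shape[1], wy.shape[2]
    nc_index = np.repeat(np.arange(N * C), K * L)
    for mask, idx, wgt in weights:
        contrib = dval * wgt * mask[:, None]
        idx_b = np.broadcast_to(idx.reshape(N, 1, K * L), (N, C, K * L))
        np.add.at(
            dx.reshape(N * C, H * W),
            (nc_index, idx_b.reshape(-1)),
            contrib.reshape(-1),
        )
    dx = dx.reshape(N, C, H, W)
    dv_dy = (-(1 - wx_) * v00 - wx_ * v01 + (1 - wx_) * v10 + wx_ * v11)
    dv_dx = (-(1 - wy_) * v00 + (1 - wy_) * v01 - wy_ * v10 + wy_ * v11)
    dpy = (dval * dv_dy).sum(axis=1)
    dpx = (dval * dv_dx).sum(axis=1)
    return dx, dpy, dpx


def deformable_conv2d(x, weight, offsets, bias=None, stride: int = 1,
                      padding: int = 0) -> Tensor:
    """Deformable convolution: y(p) = sum_k w(p_k) * x(p + p_k + dp_k).

    Each kernel tap p_k of the regular receptive field is displaced by a
    learned, spatially varying offset dp_k; fractional positions are read
    through bilinear interpolation.  ``offsets`` has shape (N, 2K, Ho, Wo)
    with (row, col) displacement pairs interleaved per tap.
    """
    x, weight, offsets = as_tensor(x), as_tensor(weight), as_tensor(offsets)
    N, C, H, W = x.data.shape
    Co, Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"weight expects {Cw} input channels, got {C}")
    K = kh * kw
    Ho, Wo = _out_size(H, kh, stride, padding), _out_size(W, kw, stride, padding)
    if offsets.data.shape != (N, 2 * K, Ho, Wo):
        raise ValueError(
            f"offset field must have shape {(N, 2 * K, Ho, Wo)} "
            f"(2 per kernel tap), got {offsets.data.shape}"
        )
    off = offsets.data.reshape(N, K, 2, Ho, Wo)
    ki, kj = np.meshgrid(np.arange(kh), np.arange(kw), indexing="ij")
    base_y = (np.arange(Ho) * stride - padding)[None, None, :, None] + \
        ki.reshape(1, K, 1, 1)
    base_x = (np.arange(Wo) * stride - padding)[None, None, None, :] + \
        kj.reshape(1, K, 1, 1)
    py = (base_y + off[:, :, 0]).reshape(N, K, Ho * Wo)
    px = (base_x + off[:, :, 1]).reshape(N, K, Ho * Wo)
    sampled, cache = bilinear_sample_map(x.data, py, px)  # N,C,K,L
    wmat = weight.data.reshape(Co, C * K)
    out_data = np.matmul(wmat[None], sampled.reshape(N, C * K, Ho * Wo))
    out_data = out_data.reshape(N, Co, Ho, Wo)
    parents = [x, weight, offsets]
    if bias is not None:
        bias = as_tensor(bias)
        out_data = out_data + bias.data.reshape(1, Co, 1, 1)
        parents.append(bias)
    out = _make(out_data, tuple(parents))
    if out._parents:
        def bw(g):
            gf = g.reshape(N, Co, Ho * Wo)
            if weight.requires_grad or weight._parents:
                dw = np.einsum("nol,nkl->ok", gf, sampled.reshape(N, C * K, -1))
                weight._accumulate(dw.reshape(weight.data.shape))
            need_x = x.requires_grad or x._parents
            need_off = offsets.requires_grad or offsets._parents
            if need_x or need_off:
                dsampled = np.matmul(wmat.T[None], gf).reshape(N, C, K, Ho * Wo)
                dx, dpy, dpx = _bilinear_backward(dsampled, cache)
                if need_x:
                    x._accumulate(dx)
                if need_off:
                    doff = np.stack(
                        [dpy.reshape(N, K, Ho, Wo), dpx.reshape(N, K, Ho, Wo)],
                        axis=2,
                    )
                    offsets._accumulate(doff.reshape(N, 2 * K, Ho, Wo))
            if bias is not None and (bias.requires_grad or bias._parents):
                bias._accumulate(g.sum(axis=(0, 2, 3)).reshape(bias.data.shape))
        out._backward = bw
    return out


def gradient_scale(x, factor: float) -> Tensor:
    """Identity in the forward pass; multiplies the backpropagated gradient
    by ``factor``.  Used to weight the classification gradient entering the
    shape encoder relative to the segmentation gradient."""
    x = as_tensor(x)
    if not (np.isscalar(factor) and factor > 0):
        raise ValueError("gradient scale factor must be a positive scalar")
    out = _make(x.data.copy(), (x,))
    if out._parents:
        out._backward = lambda g: x._accumulate(g * factor)
    return out
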