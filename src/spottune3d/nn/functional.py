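"""Volumetric neural-network primitives with custom gradients.

Convolution uses an explicit column expansion (im2col) so the inner loop is
a single BLAS matmul; the backward pass re-uses the same kernel-offset loop
to scatter gradients back (col2im). Shapes follow the (batch, channel,
depth, height, width) convention.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .tensor import Tensor

__all__ = ["conv3d", "max_pool3d", "batch_norm", "global_avg_pool", "linear",
           "binary_cross_entropy_with_logits"]


def _out_len(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _im2col(xp: np.ndarray, k: int, s: int, out_sp: tuple[int, int, int]) -> np.ndarray:
    """(B, C, D, H, W) padded input -> columns (B, C, k^3, P)."""
    B, C = xp.shape[:2]
    Do, Ho, Wo = out_sp
    cols = np.empty((B, C, k * k * k, Do * Ho * Wo), dtype=xp.dtype)
    i = 0
    for kz, ky, kx in product(range(k), repeat=3):
        patch = xp[:, :, kz:kz + s * Do:s, ky:ky + s * Ho:s, kx:kx + s * Wo:s]
        cols[:, :, i, :] = patch.reshape(B, C, -1)
        i += 1
    return cols


def _col2im(dcols: np.ndarray, xp_shape: tuple, k: int, s: int,
            out_sp: tuple[int, int, int]) -> np.ndarray:
    B, C = xp_shape[:2]
    Do, Ho, Wo = out_sp
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    i = 0
    for kz, ky, kx in product(range(k), repeat=3):
        dxp[:, :, kz:kz + s * Do:s, ky:ky + s * Ho:s, kx:kx + s * Wo:s] += \
            dcols[:, :, i, :].reshape(B, C, Do, Ho, Wo)
        i += 1
    return dxp


def conv3d(x: Tensor, weight: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation. weight: (Cout, Cin, k, k, k), cubic kernel."""
    k = weight.shape[2]
    B, C = x.shape[:2]
    Cout = weight.shape[0]
    pad = padding
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x.data
    out_sp = tuple(_out_len(n, k, stride, 0) for n in xp.shape[2:])
    cols = _im2col(xp, k, stride, out_sp)                       # (B, C, k3, P)
    colsf = cols.reshape(B, C * k ** 3, -1)                     # (B, CK, P)
    wf = weight.data.reshape(Cout, -1)                          # (Cout, CK)
    out = np.einsum("ok,bkp->bop", wf, colsf, optimize=True)
    out = out.reshape(B, Cout, *out_sp)

    def bwd(g):
        gf = g.reshape(B, Cout, -1)                             # (B, Cout, P)
        if weight.requires_grad or weight._parents:
            dw = np.einsum("bop,bkp->ok", gf, colsf, optimize=True)
            weight._accum(dw.reshape(weight.data.shape))
        if x.requires_grad or x._parents:
            dcolsf = np.einsum("ok,bop->bkp", wf, gf, optimize=True)
            dcols = dcolsf.reshape(B, C, k ** 3, -1)
            dxp = _col2im(dcols, xp.shape, k, stride, out_sp)
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
            x._accum(dxp)

    return Tensor._make(out, (x, weight), bwd)


def max_pool3d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    B, C = x.shape[:2]
    pad = padding
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3,
                constant_values=-np.inf) if pad else x.data
    out_sp = tuple(_out_len(n, kernel, stride, 0) for n in xp.shape[2:])
    cols = _im2col(xp, kernel, stride, out_sp)                  # (B, C, k3, P)
    arg = cols.argmax(axis=2)                                   # (B, C, P)
    out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]
    out = out.reshape(B, C, *out_sp)

    def bwd(g):
        dcols = np.zeros_like(cols)
        np.put_along_axis(dcols, arg[:, :, None, :], g.reshape(B, C, 1, -1), axis=2)
        dxp = _col2im(dcols, xp.shape, kernel, stride, out_sp)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
        x._accum(dxp)

    return Tensor._make(out, (x,), bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (B, spatial) for 5D input.

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running statistics are used (this is
    what keeps a frozen block's behaviour constant during training).
    """
    axes = (0, 2, 3, 4)
    shape = (1, -1, 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size / x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * n / max(n - 1, 1)
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bwd(g):
        if gamma.requires_grad or gamma._parents:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad or beta._parents:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad or x._parents:
            gi = g * gamma.data.reshape(shape)
            if training:
                n = x.data.size / x.data.shape[1]
                dxhat_sum = gi.sum(axis=axes).reshape(shape)
                dxhat_dot = (gi * xhat).sum(axis=axes).reshape(shape)
                dx = (gi - dxhat_sum / n - xhat * dxhat_dot / n) * inv.reshape(shape)
            else:
                dx = gi * inv.reshape(shape)
            x._accum(dx)

    return Tensor._make(out, (x, gamma, beta), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, D, H, W) -> (B, C)."""
    return x.mean(axis=(2, 3, 4))


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    out = x.matmul(weight.transpose((1, 0)))
    if bias is not None:
        out = out + bias
    return out


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean BCE on raw logits; targets in {0,1}."""
    z = logits
    t = np.asarray(targets, dtype=z.data.dtype).reshape(z.shape)
    zd = z.data

    # loss_i = max(z,0) - z*t + log(1 + exp(-|z|))
    val = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    n = zd.size

    def bwd(g):
        s = 1.0 / (1.0 + np.exp(-zd))
        z._accum(g * (s - t) / n)

    return Tensor._make(val.mean(), (z,), bwd)
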