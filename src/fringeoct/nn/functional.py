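"""Array operations with custom backward rules built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .core import Tensor, as_tensor

__all__ = ["conv2d", "batch_norm", "avg_pool2d", "prelu", "pad2d"]


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: tuple[int, int],
                  out_hw: tuple[int, int]) -> np.ndarray:
    """Shift-and-matmul convolution (cross-correlation) on padded input."""
    n, ci, _, _ = x.shape
    co, _, kh, kw = w.shape
    sh, sw = stride
    ho, wo = out_hw
    out = np.zeros((n, co, ho, wo), dtype=x.dtype)
    for ky in range(kh):
        for kx in range(kw):
            xs = x[:, :, ky: ky + sh * ho: sh, kx: kx + sw * wo: sw]
            out += np.einsum("nihw,oi->nohw", xs, w[:, :, ky, kx],
                             optimize=True)
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int | tuple[int, int] = 1,
           padding: int | tuple[int, int] = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, zero padding."""
    x, weight = as_tensor(x), as_tensor(weight)
    if isinstance(stride, int):
        stride = (stride, stride)
    if isinstance(padding, int):
        padding = (padding, padding)
    ph, pw = padding
    sh, sw = stride
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, ci, hp, wp = xd.shape
    co, ci_w, kh, kw = weight.data.shape
    if ci_w != ci:
        raise ValueError(f"conv2d channel mismatch: input {ci}, weight {ci_w}")
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d output would be empty")
    out_data = _conv_forward(xd, weight.data, (sh, sw), (ho, wo))

    def backward(g):
        gw = np.zeros_like(weight.data)
        gx_pad = np.zeros_like(xd)
        for ky in range(kh):
            for kx in range(kw):
                xs = xd[:, :, ky: ky + sh * ho: sh, kx: kx + sw * wo: sw]
                gw[:, :, ky, kx] = np.einsum("nihw,nohw->oi", xs, g,
                                             optimize=True)
                gx_pad[:, :, ky: ky + sh * ho: sh, kx: kx + sw * wo: sw] += \
                    np.einsum("nohw,oi->nihw", g, weight.data[:, :, ky, kx],
                              optimize=True)
        gx = gx_pad[:, :, ph: hp - ph, pw: wp - pw] if (ph or pw) else gx_pad
        return gx, gw

    out = Tensor._make(out_data, (x, weight), backward)
    if bias is not None:
        out = out + bias.reshape(1, co, 1, 1)
    return out


def pad2d(x: Tensor, padding: tuple[int, int]) -> Tensor:
    """Zero padding of the two trailing (spatial) axes."""
    x = as_tensor(x)
    ph, pw = padding
    d = x.data

    def backward(g):
        return (g[:, :, ph: ph + d.shape[2], pw: pw + d.shape[3]],)

    return Tensor._make(
        np.pad(d, ((0, 0), (0, 0), (ph, ph), (pw, pw))), (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1.0e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W); NCHW layout.

    Running statistics are updated in place during training and used
    verbatim in eval mode.
    """
    x = as_tensor(x)
    d = x.data
    axes = (0, 2, 3)
    if training:
        mean = d.mean(axis=axes)
        var = d.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (d - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    m = d.shape[0] * d.shape[2] * d.shape[3]

    def backward(g):
        gg = gamma.data[None, :, None, None]
        g_beta = g.sum(axis=axes)
        g_gamma = (g * xhat).sum(axis=axes)
        g_xhat = g * gg
        if training:
            gx = (inv_std[None, :, None, None] / m) * (
                m * g_xhat
                - g_xhat.sum(axis=axes)[None, :, None, None]
                - xhat * (g_xhat * xhat).sum(axis=axes)[None, :, None, None])
        else:
            gx = g_xhat * inv_std[None, :, None, None]
        return gx, g_gamma, g_beta

    return Tensor._make(out_data, (x, gamma, beta), backward)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU with a learnable per-channel negative slope."""
    x, slope = as_tensor(x), as_tensor(slope)
    pos = x.data > 0
    s = slope.data[None, :, None, None]
    out_data = np.where(pos, x.data, s * x.data)

    def backward(g):
        gx = np.where(pos, g, s * g)
        gs = np.where(pos, 0.0, g * x.data).sum(axis=(0, 2, 3))
        return gx, gs

    return Tensor._make(out_data, (x, slope), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling (truncates ragged edges)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    d = x.data[:, :, : ho * k, : wo * k]
    out_data = d.reshape(n, c, ho, k, wo, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.zeros_like(x.data)
        expanded = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        gx[:, :, : ho * k, : wo * k] = expanded
        return (gx,)

    return Tensor._make(out_data, (x,), backward)
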