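"""Tensor primitives with explicit backward passes.

All activations use NCHW layout.  Convolution is implemented by im2col +
one matmul; its input gradient is reassembled by slice-accumulation over
the (small) kernel footprint, which keeps both directions inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, Ho, Wo, kh, kw)
    n, c, ho, wo, _, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)
    return cols, ho, wo


def conv2d_forward(x, w, b, stride=1, pad=0):
    """x (N,C,H,W), w (F,C,kh,kw), b (F,) -> y (N,F,Ho,Wo) plus cache."""
    f, c, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, stride, pad)
    y = cols @ w.reshape(f, -1).T + b
    n = x.shape[0]
    y = y.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    cache = (x.shape, cols, w, stride, pad, ho, wo)
    return y, cache


def conv2d_backward(dy, cache):
    xshape, cols, w, stride, pad, ho, wo = cache
    n, c, h, wd = xshape
    f, _, kh, kw = w.shape
    dyc = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * ho * wo, f)
    dw = (dyc.T @ cols).reshape(f, c, kh, kw)
    db = dyc.sum(axis=0)
    dcols = dyc @ w.reshape(f, -1)  # (N*Ho*Wo, C*kh*kw)
    dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    hp, wp = h + 2 * pad, wd + 2 * pad
    dxp = np.zeros((n, c, hp, wp), dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                :, :, :, :, i, j
            ]
    dx = dxp[:, :, pad : hp - pad, pad : wp - pad] if pad else dxp
    return dx, dw, db


def relu_forward(x):
    y = np.maximum(x, 0)
    return y, (x > 0)


def relu_backward(dy, mask):
    return dy * mask


def maxpool_forward(x, k, stride, pad=0):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = win.shape
    flat = win.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    cache = ((n, c, h, w), idx, k, stride, pad, ho, wo)
    return y, cache


def maxpool_backward(dy, cache):
    (n, c, h, w), idx, k, stride, pad, ho, wo = cache
    hp, wp = h + 2 * pad, w + 2 * pad
    dxp = np.zeros((n, c, hp, wp), dtype=dy.dtype)
    oy, ox = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
    iy = oy * stride + idx // k  # (N,C,Ho,Wo) rows in padded input
    ix = ox * stride + idx % k
    ni = np.arange(n)[:, None, None, None]
    ci = np.arange(c)[None, :, None, None]
    np.add.at(dxp, (ni, ci, iy, ix), dy)
    return dxp[:, :, pad : hp - pad, pad : wp - pad] if pad else dxp


def groupnorm_forward(x, gamma, beta, groups, eps=1e-5):
    """Group normalization over (C/G, H, W) per sample and group.

    No running statistics: behavior is identical in training and evaluation,
    which keeps episodic inner-loop adaptation deterministic.
    """
    n, c, h, w = x.shape
    g = groups
    xg = x.reshape(n, g, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, inv, gamma, g)


def groupnorm_backward(dy, cache):
    xhat, inv, gamma, g = cache
    n, c, h, w = dy.shape
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = (dy * gamma[None, :, None, None]).reshape(n, g, -1)
    xh = xhat.reshape(n, g, -1)
    m = dxhat.shape[2]
    dx = inv * (dxhat - dxhat.mean(axis=2, keepdims=True) - xh * (dxhat * xh).sum(axis=2, keepdims=True) / m)
    return dx.reshape(n, c, h, w), dgamma, dbeta


def gap_forward(x):
    """Global average pool (N,C,H,W) -> (N,C)."""
    n, c, h, w = x.shape
    return x.mean(axis=(2, 3)), (n, c, h, w)


def gap_backward(dy, cache):
    n, c, h, w = cache
    return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(dy.dtype).copy()


def linear_forward(x, w, b):
    """x (N,D), w (K,D), b (K,)."""
    return x @ w.T + b, (x, w)


def linear_backward(dy, cache):
    x, w = cache
    return dy @ w, dy.T @ x, dy.sum(axis=0)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent_forward(z, y_onehot, eps=1e-12):
    """Mean cross-entropy over the batch; returns (loss, probs, cache)."""
    p = softmax(z)
    n = z.shape[0]
    loss = float(-np.sum(y_onehot * np.log(np.maximum(p, eps))) / n)
    return loss, p, (p, y_onehot, n)


def softmax_xent_backward(cache, weight=1.0):
    p, y, n = cache
    return (weight / n) * (p - y).astype(p.dtype)
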