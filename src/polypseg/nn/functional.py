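"""Low-level array operations for the segmentation networks.

All spatial tensors use the (N, C, H, W) layout in float32. Convolutions are
same-padded: the output of every operation here preserves the input's spatial
resolution, which is what lets a mirrored encoder/decoder cancel exactly.

Convolution is evaluated as a sum of kernel-tap shifts, each tap a batched
matrix product, so the heavy lifting is delegated to BLAS without the memory
cost of a full im2col buffer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "batchnorm",
    "batchnorm_backward",
    "relu",
    "relu_backward",
    "maxpool2x2",
    "maxunpool2x2",
    "softmax_channels",
    "cross_entropy",
]


def _same_pad(kernel_size: int, dilation: int) -> int:
    if kernel_size % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {kernel_size}")
    return dilation * (kernel_size - 1) // 2


def _im2col(xp: np.ndarray, kh: int, kw: int, dilation: int,
            h: int, w: int) -> np.ndarray:
    """Stack the k*k shifted views of the padded input as a
    (k*k*Cin, N*H*W) matrix (tap-major row blocks)."""
    n, cin = xp.shape[:2]
    cols = np.empty((kh * kw * cin, n * h * w), dtype=np.float32)
    t = 0
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i * dilation:i * dilation + h,
                       j * dilation:j * dilation + w]
            cols[t * cin:(t + 1) * cin] = \
                patch.transpose(1, 0, 2, 3).reshape(cin, -1)
            t += 1
    return cols


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
           dilation: int = 1, return_cache: bool = False):
    """Same-padded 2-D convolution with optional dilation.

    x      : (N, Cin, H, W)
    weight : (Cout, Cin, k, k)
    bias   : (Cout,)

    The kernel taps are spaced ``dilation`` cells apart; padding equals
    ``dilation * (k - 1) // 2`` so the output is always (N, Cout, H, W).
    Evaluated as one im2col GEMM so the arithmetic lands in BLAS.
    """
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    pad = _same_pad(kh, dilation)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, kh, kw, dilation, h, w)
    # rows of ``cols`` are (tap, cin)-ordered; match with (cout, tap, cin)
    wmat = weight.transpose(0, 2, 3, 1).reshape(cout, -1)
    out2 = wmat @ cols
    out2 += bias.astype(np.float32)[:, None]
    out = np.ascontiguousarray(
        out2.reshape(cout, n, h, w).transpose(1, 0, 2, 3))
    if return_cache:
        return out, xp
    return out


def conv2d_backward(gout: np.ndarray, xp: np.ndarray, weight: np.ndarray,
                    dilation: int = 1):
    """Gradients of :func:`conv2d`.

    gout : (N, Cout, H, W) upstream gradient
    xp   : the padded input cached by the forward pass (the column matrix
           is rebuilt here rather than cached, trading a little copy time
           for a much smaller training footprint)

    Returns (grad_x, grad_weight, grad_bias); grad_x has the unpadded shape.
    """
    n, cout, h, w = gout.shape
    _, cin, kh, kw = weight.shape
    pad = _same_pad(kh, dilation)
    g2 = np.ascontiguousarray(
        gout.transpose(1, 0, 2, 3).reshape(cout, n * h * w))
    grad_b = g2.sum(axis=1)
    cols = _im2col(xp, kh, kw, dilation, h, w)
    gw_flat = g2 @ cols.T  # (cout, k*k*cin)
    grad_w = np.ascontiguousarray(
        gw_flat.reshape(cout, kh, kw, cin).transpose(0, 3, 1, 2))
    wmat = weight.transpose(0, 2, 3, 1).reshape(cout, -1)
    gcols = wmat.T @ g2  # (k*k*cin, n*h*w)
    gxp = np.zeros_like(xp)
    t = 0
    for i in range(kh):
        for j in range(kw):
            block = gcols[t * cin:(t + 1) * cin].reshape(cin, n, h, w)
            gxp[:, :, i * dilation:i * dilation + h,
                j * dilation:j * dilation + w] += \
                block.transpose(1, 0, 2, 3)
            t += 1
    if pad:
        grad_x = gxp[:, :, pad:-pad, pad:-pad]
    else:
        grad_x = gxp
    return grad_x, grad_w, grad_b


def batchnorm(x, gamma, beta, running_mean, running_var,
              training: bool, momentum: float = 0.1, eps: float = 1e-5):
    """Batch normalisation over (N, H, W) per channel.

    Returns (y, cache); cache is None in inference mode. ``running_mean`` and
    ``running_var`` are updated in place during training.
    """
    if training:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    cache = (xhat, inv_std) if training else None
    return y.astype(np.float32, copy=False), cache


def batchnorm_backward(gout, cache, gamma):
    xhat, inv_std = cache
    m = gout.shape[0] * gout.shape[2] * gout.shape[3]
    grad_gamma = (gout * xhat).sum(axis=(0, 2, 3))
    grad_beta = gout.sum(axis=(0, 2, 3))
    # dL/dx for batch statistics taken over (N, H, W)
    gx = (gamma * inv_std)[None, :, None, None] / m * (
        m * gout
        - grad_beta[None, :, None, None]
        - xhat * grad_gamma[None, :, None, None]
    )
    return gx.astype(np.float32, copy=False), grad_gamma, grad_beta


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(gout, out):
    return np.where(out > 0, gout, 0.0)


def maxpool2x2(x):
    """2x2 stride-2 max pooling that records argmax positions.

    x : (N, C, H, W); odd H or W is padded internally with -inf so the
    output resolution is ceil(H/2) x ceil(W/2).

    Returns (pooled, indices) where ``indices`` holds, for every output cell,
    the flat row-major position of the window maximum in the *unpadded* input
    map. Ties break to the first occurrence in row-major window order, so
    indices are deterministic.
    """
    n, c, h, w = x.shape
    hp, wp = h + (h % 2), w + (w % 2)
    if (hp, wp) != (h, w):
        xq = np.full((n, c, hp, wp), -np.inf, dtype=np.float32)
        xq[:, :, :h, :w] = x
    else:
        xq = x
    win = xq.reshape(n, c, hp // 2, 2, wp // 2, 2)
    # candidates in row-major window order: (0,0), (0,1), (1,0), (1,1)
    cand = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hp // 2, wp // 2, 4)
    k = cand.argmax(axis=-1)  # first occurrence on ties
    pooled = np.take_along_axis(cand, k[..., None], axis=-1)[..., 0]
    oi = np.arange(hp // 2)[:, None]
    oj = np.arange(wp // 2)[None, :]
    rows = 2 * oi + k // 2
    cols = 2 * oj + k % 2
    indices = rows * w + cols  # flat index in the original (unpadded) map
    return pooled.astype(np.float32, copy=False), indices


def maxunpool2x2(pooled, indices, pre_pool_size):
    """Scatter pooled values back to their argmax positions; zeros elsewhere."""
    n, c, ph, pw = pooled.shape
    h, w = pre_pool_size
    if indices.shape != pooled.shape:
        raise ValueError("indices shape must match pooled shape")
    if indices.min() < 0 or indices.max() >= h * w:
        raise IndexError("pooling index out of range for pre-pool size")
    out = np.zeros((n, c, h * w), dtype=np.float32)
    flat_idx = indices.reshape(n, c, ph * pw)
    np.put_along_axis(out, flat_idx, pooled.reshape(n, c, ph * pw), axis=-1)
    return out.reshape(n, c, h, w)


def maxunpool2x2_backward(gout, indices):
    """Gather the gradient at the scatter targets (inverse of the scatter)."""
    n, c, h, w = gout.shape
    flat = gout.reshape(n, c, h * w)
    g = np.take_along_axis(flat, indices.reshape(n, c, -1), axis=-1)
    return g.reshape(indices.shape)


def softmax_channels(x):
    """Numerically stable softmax along the channel axis of (N, C, H, W)."""
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs, labels, eps: float = 1e-12):
    """Mean over pixels of -log p(true class).

    probs  : (N, C, H, W) per-pixel distributions
    labels : (N, H, W) integer class map
    """
    n, c, h, w = probs.shape
    p_true = np.take_along_axis(probs, labels[:, None, :, :], axis=1)[:, 0]
    return float(-np.log(np.maximum(p_true, eps)).mean())
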