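"""Numba kernels for the training hot path.

The dense layer of the spectral CNN holds ~12.5M weights, so optimizer and
batch-norm arithmetic is memory-bound; these fused single-pass kernels keep
the per-step traffic close to the streaming floor. All arrays are float32
and C-contiguous.
"""

from __future__ import annotations

import math

import numba
import numpy as np

_JIT = dict(fastmath=True, error_model="numpy", cache=True, nogil=True)


@numba.njit(**_JIT)
def adam_update(p, g, m, v, lr_t, b1, b2, eps2, wd):  # pragma: no cover - jit
    """One fused Adam step on flat float32 views.

    ``lr_t`` is the bias-corrected step size. The epsilon enters inside the
    square root (``denom = sqrt(v + eps^2)``), which is numerically
    equivalent to the textbook ``sqrt(v) + eps`` at the default 1e-8 and
    keeps the loop a pure fused multiply-add/rsqrt stream.
    """
    for i in range(p.size):
        gi = g[i] + wd * p[i]
        mi = b1 * m[i] + (np.float32(1.0) - b1) * gi
        vi = b2 * v[i] + (np.float32(1.0) - b2) * gi * gi
        m[i] = mi
        v[i] = vi
        p[i] -= lr_t * mi / math.sqrt(vi + eps2)


@numba.njit(**_JIT)
def bn_stats(x2, mean, var):  # pragma: no cover - jit
    """Per-channel mean and biased variance of a (rows, channels) view."""
    n, c = x2.shape
    for j in range(c):
        mean[j] = 0.0
        var[j] = 0.0
    for i in range(n):
        for j in range(c):
            mean[j] += x2[i, j]
    for j in range(c):
        mean[j] /= n
    for i in range(n):
        for j in range(c):
            d = x2[i, j] - mean[j]
            var[j] += d * d
    for j in range(c):
        var[j] /= n


@numba.njit(**_JIT)
def bn_forward(x2, mean, inv_std, gamma, beta, xhat2, out2):  # pragma: no cover
    """Normalize and affine-transform; writes both xhat (kept for backward)
    and the output."""
    n, c = x2.shape
    for i in range(n):
        for j in range(c):
            h = (x2[i, j] - mean[j]) * inv_std[j]
            xhat2[i, j] = h
            out2[i, j] = gamma[j] * h + beta[j]


@numba.njit(**_JIT)
def bn_backward(dy2, xhat2, gamma, inv_std, dgamma, dbeta, dx2):  # pragma: no cover
    """Batch-norm input gradient with the per-channel reductions fused."""
    n, c = dy2.shape
    for j in range(c):
        dgamma[j] = 0.0
        dbeta[j] = 0.0
    for i in range(n):
        for j in range(c):
            dbeta[j] += dy2[i, j]
            dgamma[j] += dy2[i, j] * xhat2[i, j]
    inv_n = np.float32(1.0) / np.float32(n)
    for i in range(n):
        for j in range(c):
            dx2[i, j] = (
                gamma[j]
                * inv_std[j]
                * (dy2[i, j] - dbeta[j] * inv_n - xhat2[i, j] * dgamma[j] * inv_n)
            )


@numba.njit(**_JIT)
def bn_relu_forward(x2, mean, inv_std, gamma, beta, xhat2, out2):  # pragma: no cover
    """Batch norm with the ReLU fused into the same pass."""
    n, c = x2.shape
    zero = np.float32(0.0)
    for i in range(n):
        for j in range(c):
            h = (x2[i, j] - mean[j]) * inv_std[j]
            xhat2[i, j] = h
            y = gamma[j] * h + beta[j]
            out2[i, j] = zero if y <= zero else y


@numba.njit(**_JIT)
def bn_relu_backward(dy2, xhat2, gamma, beta, inv_std, dgamma, dbeta, dx2):  # pragma: no cover
    """Backward pass of batch norm + ReLU; the ReLU mask is recomputed from
    the stored normalized activations instead of being stored."""
    n, c = dy2.shape
    zero = np.float32(0.0)
    for j in range(c):
        dgamma[j] = 0.0
        dbeta[j] = 0.0
    for i in range(n):
        for j in range(c):
            g = dy2[i, j] if gamma[j] * xhat2[i, j] + beta[j] > zero else zero
            dbeta[j] += g
            dgamma[j] += g * xhat2[i, j]
    inv_n = np.float32(1.0) / np.float32(n)
    for i in range(n):
        for j in range(c):
            g = dy2[i, j] if gamma[j] * xhat2[i, j] + beta[j] > zero else zero
            dx2[i, j] = (
                gamma[j]
                * inv_std[j]
                * (g - dbeta[j] * inv_n - xhat2[i, j] * dgamma[j] * inv_n)
            )
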