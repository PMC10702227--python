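"""Fused numba kernels for the autoencoder hot loop.

Minibatches are small (64 x <=256), so numpy's per-op allocation and
dispatch overhead dominates training time; these kernels fuse the batch
norm + ReLU forward/backward passes and the Adam update into a few
row-major (SIMD-friendly) passes over each array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BN_EPS = np.float32(1e-5)


@njit(cache=True, fastmath=True)
def bn_relu_forward(Z, gamma, beta):
    B, F = Z.shape
    mu = np.zeros(F, dtype=np.float32)
    var = np.zeros(F, dtype=np.float32)
    for i in range(B):
        for j in range(F):
            mu[j] += Z[i, j]
    for j in range(F):
        mu[j] /= B
    for i in range(B):
        for j in range(F):
            d = Z[i, j] - mu[j]
            var[j] += d * d
    inv_std = np.empty(F, dtype=np.float32)
    for j in range(F):
        var[j] /= B
        inv_std[j] = np.float32(1.0) / np.sqrt(var[j] + _BN_EPS)
    xhat = np.empty_like(Z)
    A = np.empty_like(Z)
    for i in range(B):
        for j in range(F):
            x = (Z[i, j] - mu[j]) * inv_std[j]
            xhat[i, j] = x
            h = gamma[j] * x + beta[j]
            A[i, j] = h if h > 0.0 else np.float32(0.0)
    return A, xhat, inv_std, mu, var


@njit(cache=True, fastmath=True)
def bn_relu_backward(dA, A, xhat, inv_std, gamma):
    B, F = dA.shape
    dgamma = np.zeros(F, dtype=np.float32)
    dbeta = np.zeros(F, dtype=np.float32)
    for i in range(B):
        for j in range(F):
            if A[i, j] > 0.0:
                dh = dA[i, j]
                dbeta[j] += dh
                dgamma[j] += dh * xhat[i, j]
    c1 = np.empty(F, dtype=np.float32)
    c2 = np.empty(F, dtype=np.float32)
    scale = np.empty(F, dtype=np.float32)
    for j in range(F):
        c1[j] = dbeta[j] / B
        c2[j] = dgamma[j] / B
        scale[j] = inv_std[j] * gamma[j]
    dZ = np.empty_like(dA)
    for i in range(B):
        for j in range(F):
            dh = dA[i, j] if A[i, j] > 0.0 else np.float32(0.0)
            dZ[i, j] = scale[j] * (dh - c1[j] - xhat[i, j] * c2[j])
    return dZ, dgamma, dbeta


@njit(cache=True, fastmath=True)
def add_l1_subgradient(d, a, lam_over_size):
    B, F = d.shape
    out = np.empty_like(d)
    for i in range(B):
        for j in range(F):
            g = np.float32(0.0)
            if a[i, j] > 0.0:
                g = lam_over_size
            elif a[i, j] < 0.0:
                g = -lam_over_size
            out[i, j] = d[i, j] + g
    return out


@njit(cache=True, fastmath=True)
def adam_update(flat, g, m, v, lr_t, one_minus_b1, one_minus_b2, eps):
    # moments of parameters with (near-)zero gradients decay geometrically
    # into float32 denormals, which stall the FPU; flush them to zero
    tiny_m = np.float32(1e-30)
    tiny_v = np.float32(1e-36)
    for i in range(flat.size):
        mi = m[i] + one_minus_b1 * (g[i] - m[i])
        vi = v[i] + one_minus_b2 * (g[i] * g[i] - v[i])
        if -tiny_m < mi < tiny_m:
            mi = np.float32(0.0)
        if vi < tiny_v:
            vi = np.float32(0.0)
        m[i] = mi
        v[i] = vi
        flat[i] -= lr_t * mi / (np.sqrt(vi) + eps)


@njit(cache=True, fastmath=True)
def upsample_linear(x, k, n):
    """Linear interpolation by integer factor k into a length-n array."""
    out = np.empty(n, dtype=np.float32)
    m = x.size
    i = 0
    for j in range(m - 1):
        a = x[j]
        step = (x[j + 1] - a) / k
        for jj in range(k):
            if i >= n:
                return out
            out[i] = a + step * jj
            i += 1
    while i < n:
        out[i] = x[m - 1]
        i += 1
    return out
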