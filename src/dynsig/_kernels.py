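"""Numba-compiled kernels for the hot loops of the neural-network engine.

Same arithmetic as the numpy reference paths in :mod:`dynsig.nn` — the LSTM
recurrence (gate order i, f, g, o) and the per-channel batch-normalization
statistics — compiled to remove interpreter overhead and temporaries.
Equivalence with the reference paths is asserted in the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward", "backward", "bn_forward_train", "bn_backward_train"]


@njit(cache=True)
def _forward(zx, Wh, u):
    B, T, U4 = zx.shape
    h = np.zeros((B, u))
    c = np.zeros((B, u))
    I = np.empty((B, T, u))
    F = np.empty((B, T, u))
    G = np.empty((B, T, u))
    O = np.empty((B, T, u))
    HP = np.empty((B, T, u))
    CP = np.empty((B, T, u))
    TC = np.empty((B, T, u))
    for t in range(T):
        z = zx[:, t] + np.dot(h, Wh)
        for b in range(B):
            for j in range(u):
                i = 1.0 / (1.0 + np.exp(-z[b, j]))
                f = 1.0 / (1.0 + np.exp(-z[b, u + j]))
                g = np.tanh(z[b, 2 * u + j])
                o = 1.0 / (1.0 + np.exp(-z[b, 3 * u + j]))
                HP[b, t, j] = h[b, j]
                CP[b, t, j] = c[b, j]
                cn = f * c[b, j] + i * g
                tc = np.tanh(cn)
                c[b, j] = cn
                h[b, j] = o * tc
                I[b, t, j] = i
                F[b, t, j] = f
                G[b, t, j] = g
                O[b, t, j] = o
                TC[b, t, j] = tc
    return h, I, F, G, O, HP, CP, TC


@njit(cache=True)
def _backward(grad, Wh, u, I, F, G, O, HP, CP, TC):
    B, T, _ = I.shape
    WhT = Wh.T.copy()
    dz_all = np.empty((B, T, 4 * u))
    dh = grad.copy()
    dc = np.zeros((B, u))
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(u):
                i = I[b, t, j]
                f = F[b, t, j]
                g = G[b, t, j]
                o = O[b, t, j]
                tc = TC[b, t, j]
                do = dh[b, j] * tc
                dcv = dc[b, j] + dh[b, j] * o * (1.0 - tc * tc)
                di = dcv * g
                df = dcv * CP[b, t, j]
                dg = dcv * i
                dz_all[b, t, j] = di * i * (1.0 - i)
                dz_all[b, t, u + j] = df * f * (1.0 - f)
                dz_all[b, t, 2 * u + j] = dg * (1.0 - g * g)
                dz_all[b, t, 3 * u + j] = do * o * (1.0 - o)
                dc[b, j] = dcv * f
        dh = np.dot(dz_all[:, t].copy(), WhT)
    return dz_all


def forward(zx, Wh, u):
    h, I, F, G, O, HP, CP, TC = _forward(np.ascontiguousarray(zx),
                                         np.ascontiguousarray(Wh), u)
    return h, (I, F, G, O, HP, CP, TC)


def backward(grad, Wh, u, I, F, G, O, HP, CP, TC):
    return _backward(grad, np.ascontiguousarray(Wh), u, I, F, G, O, HP, CP, TC)


# channel-last layout: keep c in the inner loop so memory access is contiguous
@njit(cache=True)
def bn_forward_train(x, gamma, beta, eps):
    B, L, C = x.shape
    n = B * L
    mean = np.zeros(C)
    var = np.zeros(C)
    std = np.empty(C)
    y = np.empty_like(x)
    xhat = np.empty_like(x)
    for b in range(B):
        for l in range(L):
            for c in range(C):
                mean[c] += x[b, l, c]
    mean /= n
    for b in range(B):
        for l in range(L):
            for c in range(C):
                d = x[b, l, c] - mean[c]
                var[c] += d * d
    var /= n
    for c in range(C):
        std[c] = np.sqrt(var[c] + eps)
    for b in range(B):
        for l in range(L):
            for c in range(C):
                xh = (x[b, l, c] - mean[c]) / std[c]
                xhat[b, l, c] = xh
                y[b, l, c] = gamma[c] * xh + beta[c]
    return y, mean, var, std, xhat


@njit(cache=True)
def bn_backward_train(grad, xhat, std, gamma):
    B, L, C = grad.shape
    n = B * L
    dgamma = np.zeros(C)
    dbeta = np.zeros(C)
    dx = np.empty_like(grad)
    for b in range(B):
        for l in range(L):
            for c in range(C):
                dgamma[c] += grad[b, l, c] * xhat[b, l, c]
                dbeta[c] += grad[b, l, c]
    for b in range(B):
        for l in range(L):
            for c in range(C):
                k = gamma[c] / std[c]
                dx[b, l, c] = k * (grad[b, l, c] - dbeta[c] / n
                                   - xhat[b, l, c] * dgamma[c] / n)
    return dx, dgamma, dbeta
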