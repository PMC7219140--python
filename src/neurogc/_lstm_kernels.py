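"""Numba-compiled inner loops of the fused LSTM layer.

The recurrent time loops cannot be vectorized across time, so in pure
NumPy they are dominated by per-step dispatch overhead.  These kernels
run the same arithmetic in compiled loops over time-major arrays
(T, N, ·), which keeps each step's reads and writes contiguous; the
surrounding layer code (weight projections, gradient contractions) stays
in NumPy/BLAS.  The module is optional — the layer falls back to the
NumPy path when numba is unavailable — and both paths are checked
against each other in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lstm_forward_loop", "lstm_forward_nocache", "lstm_backward_loop"]


@njit(cache=True, fastmath=True)
def lstm_forward_nocache(Zx, WhT):
    """Inference-only gate recursions: returns hidden states only.

    Skips the activation caches the training path needs, roughly halving
    memory traffic; used for prediction and surrogate scoring.
    """
    T, N, F = Zx.shape
    H = F // 4
    h = np.zeros((N, H))
    c = np.zeros((N, H))
    Hs = np.empty((T, N, H))
    for t in range(T):
        z = Zx[t] + np.dot(h, WhT)
        for n in range(N):
            for k in range(H):
                i = 1.0 / (1.0 + np.exp(-z[n, k]))
                f = 1.0 / (1.0 + np.exp(-z[n, H + k]))
                o = 1.0 / (1.0 + np.exp(-z[n, 2 * H + k]))
                g = np.tanh(z[n, 3 * H + k])
                c[n, k] = f * c[n, k] + i * g
                h[n, k] = o * np.tanh(c[n, k])
                Hs[t, n, k] = h[n, k]
    return Hs


@njit(cache=True, fastmath=True)
def lstm_forward_loop(Zx, WhT):
    """Gate recursions from precomputed input projections (time-major).

    Zx : (T, N, 4H) = X @ Wx.T + b, gate order [i, f, o, g]
    WhT : (H, 4H) transposed hidden weights
    Returns (Hs, gates, c_prev_seq, tanh_c_seq, h_prev_seq), all time-major.
    """
    T, N, F = Zx.shape
    H = F // 4
    h = np.zeros((N, H))
    c = np.zeros((N, H))
    Hs = np.empty((T, N, H))
    gates = np.empty((T, N, F))
    cps = np.empty((T, N, H))
    tcs = np.empty((T, N, H))
    hps = np.empty((T, N, H))
    for t in range(T):
        z = Zx[t] + np.dot(h, WhT)
        for n in range(N):
            for k in range(H):
                i = 1.0 / (1.0 + np.exp(-z[n, k]))
                f = 1.0 / (1.0 + np.exp(-z[n, H + k]))
                o = 1.0 / (1.0 + np.exp(-z[n, 2 * H + k]))
                g = np.tanh(z[n, 3 * H + k])
                gates[t, n, k] = i
                gates[t, n, H + k] = f
                gates[t, n, 2 * H + k] = o
                gates[t, n, 3 * H + k] = g
                cps[t, n, k] = c[n, k]
                hps[t, n, k] = h[n, k]
                cn = f * c[n, k] + i * g
                tc = np.tanh(cn)
                tcs[t, n, k] = tc
                c[n, k] = cn
                h[n, k] = o * tc
                Hs[t, n, k] = h[n, k]
    return Hs, gates, cps, tcs, hps


@njit(cache=True, fastmath=True)
def lstm_backward_loop(dHp, gates, cps, tcs, Wh):
    """Reverse sweep: per-step gate gradients DZ (T, N, 4H), time-major.

    dHp is the hidden-state gradient in processing order; Wh is (4H, H).
    """
    T, N, H = dHp.shape
    DZ = np.empty((T, N, 4 * H))
    dh_next = np.zeros((N, H))
    dc_next = np.zeros((N, H))
    for t in range(T - 1, -1, -1):
        for n in range(N):
            for k in range(H):
                i = gates[t, n, k]
                f = gates[t, n, H + k]
                o = gates[t, n, 2 * H + k]
                g = gates[t, n, 3 * H + k]
                tc = tcs[t, n, k]
                dh = dHp[t, n, k] + dh_next[n, k]
                do = dh * tc
                dc = dc_next[n, k] + dh * o * (1.0 - tc * tc)
                DZ[t, n, k] = (dc * g) * i * (1.0 - i)
                DZ[t, n, H + k] = (dc * cps[t, n, k]) * f * (1.0 - f)
                DZ[t, n, 2 * H + k] = do * o * (1.0 - o)
                DZ[t, n, 3 * H + k] = (dc * i) * (1.0 - g * g)
                dc_next[n, k] = dc * f
        dh_next = np.dot(DZ[t], Wh)
    return DZ
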