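"""Numba-compiled direct convolution kernels.

Channel counts in this model are small, which makes im2col + GEMM
bandwidth-bound; direct row-accumulating loops are faster here.  All
kernels take the spatially pre-padded input ``xp`` (NCHW, float32) and are
valid-mode with stride 1.  ``segnet.nn`` falls back to a pure-numpy path
when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@njit(fastmath=True)
def conv2d_fwd(xp, W, b):
    n, ci, hp, wp = xp.shape
    co, _, k, _ = W.shape
    ho = hp - k + 1
    wo = wp - k + 1
    y = np.empty((n, co, ho, wo), dtype=np.float32)
    row = np.empty(wo, dtype=np.float32)
    for nn in range(n):
        for oc in range(co):
            for i in range(ho):
                for j in range(wo):
                    row[j] = b[oc]
                for ic in range(ci):
                    for ki in range(k):
                        xrow = xp[nn, ic, i + ki]
                        for kj in range(k):
                            w = W[oc, ic, ki, kj]
                            for j in range(wo):
                                row[j] += w * xrow[j + kj]
                for j in range(wo):
                    y[nn, oc, i, j] = row[j]
    return y


@njit(fastmath=True)
def conv2d_bwd_dx(dy, W, hp, wp):
    n, co, ho, wo = dy.shape
    _, ci, k, _ = W.shape
    dxp = np.zeros((n, ci, hp, wp), dtype=np.float32)
    for nn in range(n):
        for ic in range(ci):
            for oc in range(co):
                for ki in range(k):
                    for kj in range(k):
                        w = W[oc, ic, ki, kj]
                        for i in range(ho):
                            drow = dy[nn, oc, i]
                            arow = dxp[nn, ic, i + ki]
                            for j in range(wo):
                                arow[j + kj] += w * drow[j]
    return dxp


@njit(fastmath=True)
def conv2d_bwd_dw(dy, xp, k):
    n, co, ho, wo = dy.shape
    ci = xp.shape[1]
    dW = np.zeros((co, ci, k, k), dtype=np.float32)
    db = np.zeros(co, dtype=np.float32)
    for nn in range(n):
        for oc in range(co):
            for i in range(ho):
                drow = dy[nn, oc, i]
                for j in range(wo):
                    db[oc] += drow[j]
                for ic in range(ci):
                    for ki in range(k):
                        xrow = xp[nn, ic, i + ki]
                        for kj in range(k):
                            s = np.float32(0.0)
                            for j in range(wo):
                                s += drow[j] * xrow[j + kj]
                            dW[oc, ic, ki, kj] += s
    return dW, db
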