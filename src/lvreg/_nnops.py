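"""Numba kernels for the convolution and pooling hot paths.

Single-threaded loop kernels that LLVM vectorises well; used by
:mod:`lvreg.nn` when numba is importable.  The NumPy implementations in
``nn.py`` remain the reference fallback.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _conv3x3_fwd(xp, w, b, y):
    n_b, c_in, _, _ = xp.shape
    c_out = w.shape[3]
    h, wd = y.shape[2], y.shape[3]
    for n in range(n_b):
        for co in range(c_out):
            for i in range(h):
                for j in range(wd):
                    y[n, co, i, j] = b[co]
        for ci in range(c_in):
            for di in range(3):
                for dj in range(3):
                    for co in range(c_out):
                        wk = w[ci, di, dj, co]
                        for i in range(h):
                            for j in range(wd):
                                y[n, co, i, j] += wk * xp[n, ci, i + di, j + dj]


def _conv3x3_bwd(xp, w, g, dw, db, dxp):
    n_b, c_in, _, _ = xp.shape
    c_out = w.shape[3]
    h, wd = g.shape[2], g.shape[3]
    for n in range(n_b):
        for co in range(c_out):
            for i in range(h):
                for j in range(wd):
                    db[co] += g[n, co, i, j]
        for ci in range(c_in):
            for di in range(3):
                for dj in range(3):
                    for co in range(c_out):
                        wk = w[ci, di, dj, co]
                        acc = 0.0
                        for i in range(h):
                            for j in range(wd):
                                gv = g[n, co, i, j]
                                acc += gv * xp[n, ci, i + di, j + dj]
                                dxp[n, ci, i + di, j + dj] += wk * gv
                        dw[ci, di, dj, co] += acc


def _pool2_fwd(x, y, idx):
    n_b, c, h, w = x.shape
    for n in range(n_b):
        for ci in range(c):
            for i in range(h // 2):
                for j in range(w // 2):
                    best = x[n, ci, 2 * i, 2 * j]
                    bk = 0
                    k = 1
                    for di in range(2):
                        for dj in range(2):
                            if di == 0 and dj == 0:
                                continue
                            v = x[n, ci, 2 * i + di, 2 * j + dj]
                            if v > best:
                                best = v
                                bk = k
                            k += 1
                    # bk encodes (di, dj) in row-major order skipping (0,0)
                    y[n, ci, i, j] = best
                    idx[n, ci, i, j] = bk


def _pool2_bwd(g, idx, dx):
    n_b, c, h2, w2 = g.shape
    for n in range(n_b):
        for ci in range(c):
            for i in range(h2):
                for j in range(w2):
                    k = idx[n, ci, i, j]
                    if k == 0:
                        di, dj = 0, 0
                    elif k == 1:
                        di, dj = 0, 1
                    elif k == 2:
                        di, dj = 1, 0
                    else:
                        di, dj = 1, 1
                    dx[n, ci, 2 * i + di, 2 * j + dj] = g[n, ci, i, j]


if HAVE_NUMBA:
    _conv3x3_fwd = numba.njit(cache=True, fastmath=True)(_conv3x3_fwd)
    _conv3x3_bwd = numba.njit(cache=True, fastmath=True)(_conv3x3_bwd)
    _pool2_fwd = numba.njit(cache=True)(_pool2_fwd)
    _pool2_bwd = numba.njit(cache=True)(_pool2_bwd)


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """y = conv(x, w) + b with zero padding 1; returns (y, padded input)."""
    n, c, h, wd = x.shape
    xp = np.zeros((n, c, h + 2, wd + 2), dtype=np.float32)
    xp[:, :, 1:-1, 1:-1] = x
    y = np.empty((n, w.shape[3], h, wd), dtype=np.float32)
    _conv3x3_fwd(xp, w, b, y)
    return y, xp


def conv3x3_backward(xp: np.ndarray, w: np.ndarray, g: np.ndarray):
    """Gradients (dw, db, dx) of the padded-conv forward pass."""
    dw = np.zeros_like(w)
    db = np.zeros(w.shape[3], dtype=np.float32)
    dxp = np.zeros_like(xp)
    _conv3x3_bwd(xp, w, np.ascontiguousarray(g, dtype=np.float32), dw, db, dxp)
    return dw, db, dxp[:, :, 1:-1, 1:-1]


def pool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    y = np.empty((n, c, h // 2, w // 2), dtype=np.float32)
    idx = np.empty((n, c, h // 2, w // 2), dtype=np.int8)
    _pool2_fwd(x, y, idx)
    return y, idx


def pool2_backward(g: np.ndarray, idx: np.ndarray, shape):
    dx = np.zeros(shape, dtype=np.float32)
    _pool2_bwd(np.ascontiguousarray(g, dtype=np.float32), idx, dx)
    return dx
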