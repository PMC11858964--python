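"""Numba-compiled inner loops for stride-1 'same' convolutions.

The kernels zero-pad internally (a cheap in-JIT copy) so the hot loops run
branch-free over fixed trip counts and auto-vectorize. The input-gradient
pass reuses the forward kernel on the spatially flipped, channel-transposed
weights (the exact adjoint for stride-1 zero-padded correlation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["correlate2d", "correlate3d", "weight_grad2d", "weight_grad3d"]


@njit(cache=True)
def _pad2d(xin, ph, pw):
    N, C, H, W = xin.shape
    xp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=xin.dtype)
    for n in range(N):
        for c in range(C):
            for y in range(H):
                xp[n, c, y + ph, pw:pw + W] = xin[n, c, y]
    return xp


@njit(cache=True)
def _pad3d(xin, pd, ph, pw):
    N, C, D, H, W = xin.shape
    xp = np.zeros((N, C, D + 2 * pd, H + 2 * ph, W + 2 * pw), dtype=xin.dtype)
    for n in range(N):
        for c in range(C):
            for z in range(D):
                for y in range(H):
                    xp[n, c, z + pd, y + ph, pw:pw + W] = xin[n, c, z, y]
    return xp


@njit(cache=True, fastmath=True)
def _corr2d(xp, w, out):
    # output row stays hot in cache while all (c, ky, kx) taps accumulate
    N, O, H, W = out.shape
    kh, kw = w.shape[2], w.shape[3]
    C = w.shape[1]
    for n in range(N):
        for o in range(O):
            for y in range(H):
                row = out[n, o, y]
                for c in range(C):
                    for ky in range(kh):
                        xrow = xp[n, c, y + ky]
                        for kx in range(kw):
                            wv = w[o, c, ky, kx]
                            for x in range(W):
                                row[x] += wv * xrow[x + kx]


@njit(cache=True, fastmath=True)
def _corr3d(xp, w, out):
    N, O, D, H, W = out.shape
    kd, kh, kw = w.shape[2], w.shape[3], w.shape[4]
    C = w.shape[1]
    for n in range(N):
        for o in range(O):
            for z in range(D):
                for y in range(H):
                    row = out[n, o, z, y]
                    for c in range(C):
                        for kz in range(kd):
                            for ky in range(kh):
                                xrow = xp[n, c, z + kz, y + ky]
                                for kx in range(kw):
                                    wv = w[o, c, kz, ky, kx]
                                    for x in range(W):
                                        row[x] += wv * xrow[x + kx]


@njit(cache=True, fastmath=True)
def _wgrad2d(xp, g, dw):
    N, O, H, W = g.shape
    kh, kw = dw.shape[2], dw.shape[3]
    C = dw.shape[1]
    for n in range(N):
        for o in range(O):
            for c in range(C):
                for ky in range(kh):
                    for kx in range(kw):
                        s = 0.0
                        for y in range(H):
                            grow = g[n, o, y]
                            xrow = xp[n, c, y + ky]
                            for x in range(W):
                                s += grow[x] * xrow[x + kx]
                        dw[o, c, ky, kx] += s


@njit(cache=True, fastmath=True)
def _wgrad3d(xp, g, dw):
    N, O, D, H, W = g.shape
    kd, kh, kw = dw.shape[2], dw.shape[3], dw.shape[4]
    C = dw.shape[1]
    for n in range(N):
        for o in range(O):
            for c in range(C):
                for kz in range(kd):
                    for ky in range(kh):
                        for kx in range(kw):
                            s = 0.0
                            for z in range(D):
                                for y in range(H):
                                    grow = g[n, o, z, y]
                                    xrow = xp[n, c, z + kz, y + ky]
                                    for x in range(W):
                                        s += grow[x] * xrow[x + kx]
                            dw[o, c, kz, ky, kx] += s


@njit(cache=True)
def _leaky_fwd(x, slope, out):
    for i in range(x.size):
        v = x[i]
        out[i] = v if v > 0 else slope * v


@njit(cache=True)
def _leaky_bwd(x, slope, g, out):
    for i in range(x.size):
        out[i] = g[i] if x[i] > 0 else slope * g[i]


def leaky_forward(x: np.ndarray, slope: float) -> np.ndarray:
    out = np.empty_like(x)
    _leaky_fwd(x.ravel(), x.dtype.type(slope), out.ravel())
    return out


def leaky_backward(x: np.ndarray, slope: float, g: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    _leaky_bwd(x.ravel(), x.dtype.type(slope), np.ascontiguousarray(g).ravel(),
               out.ravel())
    return out


@njit(cache=True)
def gather2d(img, yi, xi, wv, out):
    # out (P, C) += wv[:, None] * img[:, yi, xi].T without fancy-index temps
    C = img.shape[0]
    P = yi.shape[0]
    for p in range(P):
        w = wv[p]
        y = yi[p]
        x = xi[p]
        for c in range(C):
            out[p, c] += w * img[c, y, x]


@njit(cache=True)
def scatter_add2d(target, yi, xi, wv, g):
    # target (H, W, C) += at (yi, xi) the rows wv[:, None] * g
    P, C = g.shape
    for p in range(P):
        t = target[yi[p], xi[p]]
        w = wv[p]
        for c in range(C):
            t[c] += w * g[p, c]


def _c(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(a)


@njit(cache=True, fastmath=True)
def _corr2d_k3(xp, w, out):
    # 3x3 specialization: one fused pass per row with 9 taps
    N, O, H, W = out.shape
    C = w.shape[1]
    for n in range(N):
        for o in range(O):
            for y in range(H):
                row = out[n, o, y]
                for c in range(C):
                    r0 = xp[n, c, y]
                    r1 = xp[n, c, y + 1]
                    r2 = xp[n, c, y + 2]
                    w00 = w[o, c, 0, 0]; w01 = w[o, c, 0, 1]; w02 = w[o, c, 0, 2]
                    w10 = w[o, c, 1, 0]; w11 = w[o, c, 1, 1]; w12 = w[o, c, 1, 2]
                    w20 = w[o, c, 2, 0]; w21 = w[o, c, 2, 1]; w22 = w[o, c, 2, 2]
                    for x in range(W):
                        row[x] += (w00 * r0[x] + w01 * r0[x + 1] + w02 * r0[x + 2]
                                   + w10 * r1[x] + w11 * r1[x + 1] + w12 * r1[x + 2]
                                   + w20 * r2[x] + w21 * r2[x + 1] + w22 * r2[x + 2])


@njit(cache=True, fastmath=True)
def _corr3d_k3(xp, w, out):
    # 3x3x3 specialization: fused 9-tap row updates per kz slice
    N, O, D, H, W = out.shape
    C = w.shape[1]
    for n in range(N):
        for o in range(O):
            for z in range(D):
                for y in range(H):
                    row = out[n, o, z, y]
                    for c in range(C):
                        for kz in range(3):
                            sl = xp[n, c, z + kz]
                            r0 = sl[y]
                            r1 = sl[y + 1]
                            r2 = sl[y + 2]
                            w00 = w[o, c, kz, 0, 0]; w01 = w[o, c, kz, 0, 1]; w02 = w[o, c, kz, 0, 2]
                            w10 = w[o, c, kz, 1, 0]; w11 = w[o, c, kz, 1, 1]; w12 = w[o, c, kz, 1, 2]
                            w20 = w[o, c, kz, 2, 0]; w21 = w[o, c, kz, 2, 1]; w22 = w[o, c, kz, 2, 2]
                            for x in range(W):
                                row[x] += (w00 * r0[x] + w01 * r0[x + 1] + w02 * r0[x + 2]
                                           + w10 * r1[x] + w11 * r1[x + 1] + w12 * r1[x + 2]
                                           + w20 * r2[x] + w21 * r2[x + 1] + w22 * r2[x + 2])


@njit(cache=True, fastmath=True)
def _wgrad3d_k3(xp, g, dw):
    # 3x3x3 specialization: nine row-dot accumulators in one sweep
    N, O, D, H, W = g.shape
    C = dw.shape[1]
    for n in range(N):
        for o in range(O):
            for c in range(C):
                for kz in range(3):
                    s00 = s01 = s02 = s10 = s11 = s12 = s20 = s21 = s22 = 0.0
                    for z in range(D):
                        for y in range(H):
                            grow = g[n, o, z, y]
                            sl = xp[n, c, z + kz]
                            r0 = sl[y]
                            r1 = sl[y + 1]
                            r2 = sl[y + 2]
                            for x in range(W):
                                gv = grow[x]
                                s00 += gv * r0[x]
                                s01 += gv * r0[x + 1]
                                s02 += gv * r0[x + 2]
                                s10 += gv * r1[x]
                                s11 += gv * r1[x + 1]
                                s12 += gv * r1[x + 2]
                                s20 += gv * r2[x]
                                s21 += gv * r2[x + 1]
                                s22 += gv * r2[x + 2]
                    dw[o, c, kz, 0, 0] += s00
                    dw[o, c, kz, 0, 1] += s01
                    dw[o, c, kz, 0, 2] += s02
                    dw[o, c, kz, 1, 0] += s10
                    dw[o, c, kz, 1, 1] += s11
                    dw[o, c, kz, 1, 2] += s12
                    dw[o, c, kz, 2, 0] += s20
                    dw[o, c, kz, 2, 1] += s21
                    dw[o, c, kz, 2, 2] += s22


def pad_same(inp: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    """Zero-pad the spatial axes for a 'same' correlation with kernel k."""
    inp = _c(inp)
    if len(k) == 2:
        return _pad2d(inp, k[0] // 2, k[1] // 2)
    return _pad3d(inp, k[0] // 2, k[1] // 2, k[2] // 2)


def correlate2d(inp: np.ndarray, w: np.ndarray, n_ch: int | None = None,
                padded: bool = False) -> np.ndarray:
    """(N, C, H, W) ⋆ (O, C, kh, kw) -> (N, O, H, W), zero-padded 'same'.

    With ``padded=True`` the input is already the output of :func:`pad_same`.
    """
    k = (w.shape[2], w.shape[3])
    xp = inp if padded else pad_same(inp, k)
    N = xp.shape[0]
    H = xp.shape[2] - 2 * (k[0] // 2)
    W = xp.shape[3] - 2 * (k[1] // 2)
    out = np.zeros((N, w.shape[0], H, W), dtype=xp.dtype)
    wc = _c(w.astype(xp.dtype, copy=False))
    if k == (3, 3):
        _corr2d_k3(xp, wc, out)
    else:
        _corr2d(xp, wc, out)
    return out


def correlate3d(inp: np.ndarray, w: np.ndarray, n_ch: int | None = None,
                padded: bool = False) -> np.ndarray:
    """(N, C, D, H, W) ⋆ (O, C, kd, kh, kw) -> (N, O, D, H, W)."""
    k = (w.shape[2], w.shape[3], w.shape[4])
    xp = inp if padded else pad_same(inp, k)
    N = xp.shape[0]
    sp = tuple(xp.shape[2 + i] - 2 * (k[i] // 2) for i in range(3))
    out = np.zeros((N, w.shape[0]) + sp, dtype=xp.dtype)
    wc = _c(w.astype(xp.dtype, copy=False))
    if k == (3, 3, 3):
        _corr3d_k3(xp, wc, out)
    else:
        _corr3d(xp, wc, out)
    return out


def weight_grad2d(inp: np.ndarray, g: np.ndarray, k: tuple[int, int],
                  n_ch: int | None = None, padded: bool = False) -> np.ndarray:
    xp = inp if padded else pad_same(inp, k)
    C = n_ch if padded else inp.shape[1]
    dw = np.zeros((g.shape[1], C) + tuple(k), dtype=xp.dtype)
    _wgrad2d(xp, _c(g.astype(xp.dtype, copy=False)), dw)
    return dw


def weight_grad3d(inp: np.ndarray, g: np.ndarray, k: tuple[int, int, int],
                  n_ch: int | None = None, padded: bool = False) -> np.ndarray:
    xp = inp if padded else pad_same(inp, k)
    C = n_ch if padded else inp.shape[1]
    dw = np.zeros((g.shape[1], C) + tuple(k), dtype=xp.dtype)
    gc = _c(g.astype(xp.dtype, copy=False))
    if tuple(k) == (3, 3, 3):
        _wgrad3d_k3(xp, gc, dw)
    else:
        _wgrad3d(xp, gc, dw)
    return dw
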