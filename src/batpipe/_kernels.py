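"""Numba JIT kernels behind the :mod:`batpipe.nn` layers.

All image tensors are channels-last ``(batch, height, width, channels)``.
Each kernel makes a single pass over its large operand; on a
memory-bandwidth-limited CPU this is what makes training on full-resolution
spectrograms feasible. Two loop orderings are provided for the convolutions
so that the compiler can vectorize over whichever channel axis is wide:
``_ovec`` variants stream over output channels (wide c_out), ``_cvec``
variants reduce over input channels (wide c_in, e.g. a 1-channel output).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_JIT = dict(cache=True, fastmath=True, nogil=True)


@njit(**_JIT)
def conv2d_fwd_ovec(xp, w, b, out):
    bsz, ho, wo, c_out = out.shape
    kh, kw, c_in, _ = w.shape
    for bb in range(bsz):
        for y in range(ho):
            orow = out[bb, y]
            for x in range(wo):
                for o in range(c_out):
                    orow[x, o] = b[o]
            for i in range(kh):
                xrow = xp[bb, y + i]
                for j in range(kw):
                    for c in range(c_in):
                        wv = w[i, j, c]
                        for x in range(wo):
                            v = xrow[x + j, c]
                            acc = orow[x]
                            for o in range(c_out):
                                acc[o] += v * wv[o]


@njit(**_JIT)
def conv2d_fwd_cvec(xp, wt, b, out):
    # wt is (kh, kw, c_out, c_in): input channels contiguous for the reduction
    bsz, ho, wo, c_out = out.shape
    kh, kw, _, c_in = wt.shape
    for bb in range(bsz):
        for y in range(ho):
            for x in range(wo):
                for o in range(c_out):
                    s = b[o]
                    for i in range(kh):
                        xrow = xp[bb, y + i]
                        for j in range(kw):
                            xv = xrow[x + j]
                            wv = wt[i, j, o]
                            for c in range(c_in):
                                s += xv[c] * wv[c]
                    out[bb, y, x, o] = s


@njit(**_JIT)
def conv2d_bwd_ovec(xp, w, g, dw, db, dxp, need_dx):
    bsz, ho, wo, c_out = g.shape
    kh, kw, c_in, _ = w.shape
    for bb in range(bsz):
        for y in range(ho):
            grow = g[bb, y]
            for x in range(wo):
                for o in range(c_out):
                    db[o] += grow[x, o]
            for i in range(kh):
                xrow = xp[bb, y + i]
                dxrow = dxp[bb, y + i]
                for j in range(kw):
                    for c in range(c_in):
                        dwv = dw[i, j, c]
                        wv = w[i, j, c]
                        for x in range(wo):
                            v = xrow[x + j, c]
                            gr = grow[x]
                            s = 0.0
                            for o in range(c_out):
                                gv = gr[o]
                                dwv[o] += v * gv
                                s += gv * wv[o]
                            if need_dx:
                                dxrow[x + j, c] += s


@njit(**_JIT)
def conv2d_bwd_cvec(xp, wt, g, dwt, db, dxp, need_dx):
    # wt / dwt are (kh, kw, c_out, c_in)
    bsz, ho, wo, c_out = g.shape
    kh, kw, _, c_in = wt.shape
    for bb in range(bsz):
        for y in range(ho):
            grow = g[bb, y]
            for x in range(wo):
                for o in range(c_out):
                    db[o] += grow[x, o]
            for i in range(kh):
                xrow = xp[bb, y + i]
                dxrow = dxp[bb, y + i]
                for j in range(kw):
                    for x in range(wo):
                        xv = xrow[x + j]
                        dxv = dxrow[x + j]
                        for o in range(c_out):
                            gv = grow[x, o]
                            dwv = dwt[i, j, o]
                            wv = wt[i, j, o]
                            for c in range(c_in):
                                dwv[c] += xv[c] * gv
                            if need_dx:
                                for c in range(c_in):
                                    dxv[c] += gv * wv[c]


@njit(**_JIT)
def deconv2_fwd(x, w, b, out):
    bsz, h, wd, c_in = x.shape
    c_out = w.shape[3]
    for bb in range(bsz):
        for y in range(2 * h):
            i = y & 1
            xrow = x[bb, y >> 1]
            orow = out[bb, y]
            for xx in range(2 * wd):
                j = xx & 1
                xv = xrow[xx >> 1]
                ov = orow[xx]
                for o in range(c_out):
                    ov[o] = b[o]
                for c in range(c_in):
                    v = xv[c]
                    wv = w[i, j, c]
                    for o in range(c_out):
                        ov[o] += v * wv[o]


@njit(**_JIT)
def deconv2_bwd(x, w, g, dw, db, dx):
    bsz, h, wd, c_in = x.shape
    c_out = w.shape[3]
    for bb in range(bsz):
        for y in range(h):
            for xx in range(wd):
                xv = x[bb, y, xx]
                dxv = dx[bb, y, xx]
                for i in range(2):
                    grow = g[bb, 2 * y + i]
                    for j in range(2):
                        gv = grow[2 * xx + j]
                        for o in range(c_out):
                            db[o] += gv[o]
                        for c in range(c_in):
                            v = xv[c]
                            dwv = dw[i, j, c]
                            wv = w[i, j, c]
                            s = 0.0
                            for o in range(c_out):
                                go = gv[o]
                                dwv[o] += v * go
                                s += go * wv[o]
                            dxv[c] += s


@njit(**_JIT)
def maxpool2_fwd(x, out, idx):
    bsz, h, wd, c = x.shape
    _, ho, wo, _ = out.shape
    for bb in range(bsz):
        for y in range(ho):
            y0 = 2 * y
            y1ok = y0 + 1 < h
            for xx in range(wo):
                x0 = 2 * xx
                x1ok = x0 + 1 < wd
                for cc in range(c):
                    best = x[bb, y0, x0, cc]
                    k = 0
                    if x1ok and x[bb, y0, x0 + 1, cc] > best:
                        best = x[bb, y0, x0 + 1, cc]
                        k = 1
                    if y1ok:
                        if x[bb, y0 + 1, x0, cc] > best:
                            best = x[bb, y0 + 1, x0, cc]
                            k = 2
                        if x1ok and x[bb, y0 + 1, x0 + 1, cc] > best:
                            best = x[bb, y0 + 1, x0 + 1, cc]
                            k = 3
                    out[bb, y, xx, cc] = best
                    idx[bb, y, xx, cc] = k


@njit(**_JIT)
def maxpool2_bwd(g, idx, dx):
    bsz, ho, wo, c = g.shape
    for bb in range(bsz):
        for y in range(ho):
            for xx in range(wo):
                for cc in range(c):
                    k = idx[bb, y, xx, cc]
                    dx[bb, 2 * y + (k >> 1), 2 * xx + (k & 1), cc] += \
                        g[bb, y, xx, cc]


@njit(**_JIT)
def relu_bwd_inplace(grad, out):
    g = grad.reshape(-1)
    o = out.reshape(-1)
    for i in range(g.size):
        if o[i] <= 0:
            g[i] = 0


@njit(**_JIT)
def bn_stats(xf, sums, sumsq):
    n, c = xf.shape
    for i in range(n):
        for j in range(c):
            v = xf[i, j]
            sums[j] += v
            sumsq[j] += v * v


@njit(**_JIT)
def bn_fwd(xf, mean, inv_std, gamma, beta, xhat, out):
    n, c = xf.shape
    for i in range(n):
        for j in range(c):
            h = (xf[i, j] - mean[j]) * inv_std[j]
            xhat[i, j] = h
            out[i, j] = gamma[j] * h + beta[j]


@njit(**_JIT)
def bn_bwd_stats(gf, xhat, sg, sgx):
    n, c = gf.shape
    for i in range(n):
        for j in range(c):
            gv = gf[i, j]
            sg[j] += gv
            sgx[j] += gv * xhat[i, j]


@njit(**_JIT)
def bn_bwd(gf, xhat, scale, m1, m2, dx):
    # dx = scale * (g - m1 - xhat * m2), all per-channel coefficients
    n, c = gf.shape
    for i in range(n):
        for j in range(c):
            dx[i, j] = scale[j] * (gf[i, j] - m1[j] - xhat[i, j] * m2[j])


def warmup(dtype=np.float32) -> None:
    """Trigger JIT compilation of every kernel on tiny arrays."""
    x = np.zeros((1, 6, 6, 2), dtype=dtype)
    w = np.zeros((3, 3, 2, 2), dtype=dtype)
    b = np.zeros(2, dtype=dtype)
    out = np.zeros((1, 4, 4, 2), dtype=dtype)
    conv2d_fwd_ovec(x, w, b, out)
    conv2d_fwd_cvec(x, w, b, out)
    conv2d_bwd_ovec(x, w, out, np.zeros_like(w), np.zeros_like(b),
                    np.zeros_like(x), True)
    conv2d_bwd_cvec(x, w, out, np.zeros_like(w), np.zeros_like(b),
                    np.zeros_like(x), True)
    s64a, s64b = np.zeros(2, np.float64), np.zeros(2, np.float64)
    bn_stats(np.zeros((4, 2), dtype=dtype), s64a, s64b)
    bn_bwd_stats(np.zeros((4, 2), dtype=dtype), np.zeros((4, 2), dtype=dtype),
                 s64a.copy(), s64b.copy())
    wd = np.zeros((2, 2, 2, 2), dtype=dtype)
    o2 = np.zeros((1, 12, 12, 2), dtype=dtype)
    deconv2_fwd(x, wd, b, o2)
    deconv2_bwd(x, wd, o2, np.zeros_like(wd), np.zeros_like(b),
                np.zeros_like(x))
    relu_bwd_inplace(x.copy(), x)
    po = np.zeros((1, 3, 3, 2), dtype=dtype)
    idx = np.zeros((1, 3, 3, 2), dtype=np.uint8)
    maxpool2_fwd(x, po, idx)
    maxpool2_bwd(po, idx, np.zeros_like(x))
    xf = np.zeros((4, 2), dtype=dtype)
    s1 = np.zeros(2, dtype=dtype)
    bn_stats(xf, s1, s1.copy())
    bn_fwd(xf, s1, s1, s1, s1, np.zeros_like(xf), np.zeros_like(xf))
    bn_bwd_stats(xf, xf, s1.copy(), s1.copy())
    bn_bwd(xf, xf, s1, s1, s1, np.zeros_like(xf))
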