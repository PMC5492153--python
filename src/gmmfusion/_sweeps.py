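"""In-place Gauss-Seidel sweep kernel (numba-compiled).

One kernel serves every solver: the classic measure-field scheme is the
special case of unit edge weights with the mixture field equal to the
likelihood.  Sites are visited in fixed row-major order and updated in
place, which makes runs bit-reproducible and each sweep an exact block
of coordinate minimizations of the quadratic objective.

Edge weights are stored per unordered edge in direction arrays:
``wv[i, j]`` couples (i, j)-(i+1, j); ``wh[i, j]`` couples
(i, j)-(i, j+1); for 8-connectivity ``wd1[i, j]`` couples
(i, j)-(i+1, j+1) and ``wd2[i, j]`` couples (i, j+1)-(i+1, j).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gs_sweep(p, u, lam, wv, wh, wd1, wd2, eight):  # pragma: no cover - numba
    """One in-place row-major sweep; returns the max-abs update."""
    H, W, K = p.shape
    acc = np.empty(K)
    delta = 0.0
    for i in range(H):
        for j in range(W):
            sw = 0.0
            for k in range(K):
                acc[k] = 0.0
            if i > 0:
                w = wv[i - 1, j]
                sw += w
                for k in range(K):
                    acc[k] += w * p[i - 1, j, k]
            if i < H - 1:
                w = wv[i, j]
                sw += w
                for k in range(K):
                    acc[k] += w * p[i + 1, j, k]
            if j > 0:
                w = wh[i, j - 1]
                sw += w
                for k in range(K):
                    acc[k] += w * p[i, j - 1, k]
            if j < W - 1:
                w = wh[i, j]
                sw += w
                for k in range(K):
                    acc[k] += w * p[i, j + 1, k]
            if eight:
                if i > 0 and j > 0:
                    w = wd1[i - 1, j - 1]
                    sw += w
                    for k in range(K):
                        acc[k] += w * p[i - 1, j - 1, k]
                if i < H - 1 and j < W - 1:
                    w = wd1[i, j]
                    sw += w
                    for k in range(K):
                        acc[k] += w * p[i + 1, j + 1, k]
                if i > 0 and j < W - 1:
                    w = wd2[i - 1, j]
                    sw += w
                    for k in range(K):
                        acc[k] += w * p[i - 1, j + 1, k]
                if i < H - 1 and j > 0:
                    w = wd2[i, j - 1]
                    sw += w
                    for k in range(K):
                        acc[k] += w * p[i + 1, j - 1, k]
            denom = 1.0 + lam * sw
            for k in range(K):
                new = (u[i, j, k] + lam * acc[k]) / denom
                d = abs(new - p[i, j, k])
                if d > delta:
                    delta = d
                p[i, j, k] = new
    return delta
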