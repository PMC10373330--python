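"""Compiled proximal-gradient core for the sparse-group log-contrast fit.

The objective, in the stacked coefficient vector
``w = (a0, aX, aR, a_M, a_C)``::

    0.5/n ||y - Z w||^2
    + lam2 * sum_j sqrt(aM_j^2 + aC_j^2 + br_j^2)        (smooth: br_j > 0)
    + lam1 * (||a_M||_1 + ||a_C||_1)                     (prox, exact)
    s.t. sum(a_M) = 0, sum(a_C) = 0                      (prox, exact)

The L1 + sum-to-zero proximal step is solved exactly through its scalar
dual (piecewise-linear root in the multiplier), so iterates carry exact
zeros and exactly centered blocks. The outer loop is a monotone FISTA:
candidates that would increase the objective are rejected, so the
objective sequence is non-increasing by construction.
"""

import numpy as np
from numba import njit

__all__ = ["fista_sparse_group"]


@njit(cache=True)
def _prox_block(v, t):
    """argmin_a 0.5||a - v||^2 + t ||a||_1  s.t. sum(a) = 0."""
    j = v.shape[0]
    out = np.empty(j)
    if t <= 0.0:
        mean = 0.0
        for i in range(j):
            mean += v[i]
        mean /= j
        for i in range(j):
            out[i] = v[i] - mean
        return out
    bp = np.empty(2 * j)
    for i in range(j):
        bp[i] = v[i] - t
        bp[j + i] = v[i] + t
    bp = np.sort(bp)
    # g(mu) = sum soft(v - mu, t): non-increasing, piecewise linear
    prev_mu = bp[0]
    prev_g = 0.0
    for i in range(j):
        d = v[i] - prev_mu
        if d > t:
            prev_g += d - t
        elif d < -t:
            prev_g += d + t
    mu = prev_mu
    found = prev_g <= 0.0
    if not found:
        for idx in range(1, 2 * j):
            cur_mu = bp[idx]
            g = 0.0
            for i in range(j):
                d = v[i] - cur_mu
                if d > t:
                    g += d - t
                elif d < -t:
                    g += d + t
            if g <= 0.0:
                if prev_g > g:
                    mu = prev_mu + prev_g * (cur_mu - prev_mu) / (prev_g - g)
                else:
                    mu = 0.5 * (prev_mu + cur_mu)
                found = True
                break
            prev_mu = cur_mu
            prev_g = g
        if not found:
            mu = bp[2 * j - 1]
    ssum = 0.0
    nnz = 0
    for i in range(j):
        d = v[i] - mu
        if d > t:
            out[i] = d - t
            ssum += out[i]
            nnz += 1
        elif d < -t:
            out[i] = d + t
            ssum += out[i]
            nnz += 1
        else:
            out[i] = 0.0
    if nnz > 0:
        corr = ssum / nnz
        for i in range(j):
            if out[i] != 0.0:
                out[i] -= corr
    return out


@njit(cache=True)
def _objective(gram, zy, yy, br2, i0, j, lam1, lam2, w):
    p = w.shape[0]
    quad = yy
    for i in range(p):
        gi = 0.0
        for l in range(p):
            gi += gram[i, l] * w[l]
        quad += w[i] * (gi - 2.0 * zy[i])
    val = 0.5 * quad
    pen = 0.0
    for i in range(j):
        a = w[i0 + i]
        c = w[i0 + j + i]
        if lam2 > 0.0:
            val += lam2 * np.sqrt(a * a + c * c + br2[i])
        pen += abs(a) + abs(c)
    return val + lam1 * pen


@njit(cache=True)
def fista_sparse_group(gram, zy, yy, br2, i0, j, lam1, lam2, w0, max_iter, tol, lip):
    """Monotone FISTA; returns (w, objective, n_iter, converged)."""
    p = gram.shape[0]
    w = w0.copy()
    x_prev = w0.copy()
    grad = np.empty(p)
    if lip <= 0.0:
        lip = 1e-12
    step = 1.0 / lip
    obj = _objective(gram, zy, yy, br2, i0, j, lam1, lam2, w)
    tk = 1.0
    stall = 0
    converged = False
    it = 0
    for it in range(max_iter):
        tk_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        beta = (tk - 1.0) / tk_next
        # momentum point
        yk = np.empty(p)
        for i in range(p):
            yk[i] = w[i] + beta * (w[i] - x_prev[i])
        # smooth gradient at yk
        for i in range(p):
            gi = -zy[i]
            for l in range(p):
                gi += gram[i, l] * yk[l]
            grad[i] = gi
        if lam2 > 0.0:
            for i in range(j):
                a = yk[i0 + i]
                c = yk[i0 + j + i]
                s = np.sqrt(a * a + c * c + br2[i])
                grad[i0 + i] += lam2 * a / s
                grad[i0 + j + i] += lam2 * c / s
        z = np.empty(p)
        for i in range(p):
            z[i] = yk[i] - step * grad[i]
        za = _prox_block(z[i0 : i0 + j], step * lam1)
        zc = _prox_block(z[i0 + j : i0 + 2 * j], step * lam1)
        for i in range(j):
            z[i0 + i] = za[i]
            z[i0 + j + i] = zc[i]
        obj_z = _objective(gram, zy, yy, br2, i0, j, lam1, lam2, z)
        x_prev = w.copy()
        tk = tk_next
        if obj_z <= obj:
            rel = (obj - obj_z) / max(1.0, abs(obj))
            w = z
            obj = obj_z
            stall = 0
            if rel < tol and it > 0:
                converged = True
                break
        else:
            stall += 1
            if stall >= 2:
                step *= 0.5
                tk = 1.0
                x_prev = w.copy()
                stall = 0
                if step * lip < 1e-14:
                    break
    return w, obj, it + 1, converged
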