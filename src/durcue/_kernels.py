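"""Numba kernels for the decision function and boundary search.

These mirror the numpy formulas in :mod:`durcue.observer` (conjugate
Gaussian-mixture posteriors, P(t1 > t2), bracketed root search for the
decision boundary) in scalar loops so that model fitting, which calls the
boundary search tens of thousands of times, stays fast.  The first-position
posterior is hoisted out of the root iteration (it depends only on x1) and
prior log-weights are precomputed by the caller.  Consistency with the
numpy path is covered by tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_FLAT = 0
KIND_SINGLE = 1
KIND_DOUBLE = 2

_SQRT1_2 = 1.0 / math.sqrt(2.0)


@njit(cache=True)
def _phi(z):
    return 0.5 * (1.0 + math.erf(z * _SQRT1_2))


@njit(cache=True)
def _posterior(y, tau, mu, logw, k2, a, m):
    """Fill posterior mixture weights/means for one measurement; returns the
    (component-independent) posterior variance."""
    K = mu.size
    tsq = tau * tau
    s = tsq + k2
    best = -1e308
    for i in range(K):
        d = y - mu[i]
        a[i] = logw[i] - 0.5 * d * d / s
        if a[i] > best:
            best = a[i]
        m[i] = (k2 * y + tsq * mu[i]) / s
    tot = 0.0
    for i in range(K):
        a[i] = math.exp(a[i] - best)
        tot += a[i]
    for i in range(K):
        a[i] /= tot
    return tsq * k2 / s


@njit(cache=True)
def _cross(a1, m1, v1, a2, m2, v2):
    """P(t1 > t2) from two independent posterior mixtures."""
    denom = 1.0 / math.sqrt(v1 + v2)
    p = 0.0
    for i in range(a1.size):
        if a1[i] < 1e-14:
            continue
        acc = 0.0
        for j in range(a2.size):
            if a2[j] < 1e-14:
                continue
            acc += a2[j] * _phi((m1[i] - m2[j]) * denom)
        p += a1[i] * acc
    return p


@njit(cache=True)
def pd0_point(y1, y2, t1, t2, kind, mu_a, logw_a, mu_b, logw_b, kappa):
    """p(D=0) = P(first longer) for one measurement pair."""
    if kind == KIND_FLAT:
        return _phi((y1 - y2) / math.sqrt(t1 * t1 + t2 * t2))
    k2 = kappa * kappa
    aA1 = np.empty(mu_a.size)
    mA1 = np.empty(mu_a.size)
    aA2 = np.empty(mu_a.size)
    mA2 = np.empty(mu_a.size)
    if kind == KIND_SINGLE:
        vA1 = _posterior(y1, t1, mu_a, logw_a, k2, aA1, mA1)
        vA2 = _posterior(y2, t2, mu_a, logw_a, k2, aA2, mA2)
        return _cross(aA1, mA1, vA1, aA2, mA2, vA2)
    aB1 = np.empty(mu_b.size)
    mB1 = np.empty(mu_b.size)
    aB2 = np.empty(mu_b.size)
    mB2 = np.empty(mu_b.size)
    vA1 = _posterior(y1, t1, mu_a, logw_a, k2, aA1, mA1)
    vB1 = _posterior(y1, t1, mu_b, logw_b, k2, aB1, mB1)
    vA2 = _posterior(y2, t2, mu_a, logw_a, k2, aA2, mA2)
    vB2 = _posterior(y2, t2, mu_b, logw_b, k2, aB2, mB2)
    # O = "c-r": prior a (comparison) on position 1, prior b (reference) on 2
    p_cr = _cross(aA1, mA1, vA1, aB2, mB2, vB2)
    p_rc = _cross(aB1, mB1, vB1, aA2, mA2, vA2)
    return 0.5 * (p_cr + p_rc)


@njit(cache=True)
def pd0_points(y1, y2, t1, t2, kind, mu_a, logw_a, mu_b, logw_b, kappa):
    n = y1.size
    out = np.empty(n)
    for i in range(n):
        out[i] = pd0_point(y1[i], y2[i], t1[i], t2[i], kind,
                           mu_a, logw_a, mu_b, logw_b, kappa)
    return out


@njit(cache=True)
def _g_hoisted(y2, t2, kind, k2, aA1, mA1, vA1, aB1, mB1, vB1,
               mu_a, logw_a, mu_b, logw_b, aw2, mw2, bw2, mb2):
    """Decision function p(D=0) - 0.5 with the x1 posteriors precomputed."""
    if kind == KIND_SINGLE:
        vA2 = _posterior(y2, t2, mu_a, logw_a, k2, aw2, mw2)
        return _cross(aA1, mA1, vA1, aw2, mw2, vA2) - 0.5
    vB2 = _posterior(y2, t2, mu_b, logw_b, k2, bw2, mb2)
    vA2 = _posterior(y2, t2, mu_a, logw_a, k2, aw2, mw2)
    p_cr = _cross(aA1, mA1, vA1, bw2, mb2, vB2)
    p_rc = _cross(aB1, mB1, vB1, aw2, mw2, vA2)
    return 0.5 * (p_cr + p_rc) - 0.5


@njit(cache=True)
def boundary_kernel(y1, t1, t2, kind, mu_a, logw_a, mu_b, logw_b, kappa,
                    xtol, n_scan, do_scan):
    """Per-point bracketed root search for the x2 decision boundary.

    Brackets by doubling expansion (hard limit 8 doublings), optionally
    scans ``n_scan`` points to assert that p(D=0) is non-increasing in x2,
    then solves by safeguarded false position (Illinois) to bracket width
    ``xtol``.  Returns (roots, status, n_nonmono): status 0 = bracketed
    root, -1/+1 = the whole axis decides second/first longer (root pushed
    to -/+ infinity).
    """
    n = y1.size
    Ka = mu_a.size
    Kb = mu_b.size
    roots = np.empty(n)
    status = np.zeros(n, np.int8)
    n_nonmono = 0
    aA1 = np.empty(Ka)
    mA1 = np.empty(Ka)
    aB1 = np.empty(Kb)
    mB1 = np.empty(Kb)
    aw2 = np.empty(Ka)
    mw2 = np.empty(Ka)
    bw2 = np.empty(Kb)
    mb2 = np.empty(Kb)
    k2 = kappa * kappa
    for i in range(n):
        yy = y1[i]
        tt1 = t1[i]
        tt2 = t2[i]
        vA1 = _posterior(yy, tt1, mu_a, logw_a, k2, aA1, mA1)
        vB1 = 0.0
        if kind == KIND_DOUBLE:
            vB1 = _posterior(yy, tt1, mu_b, logw_b, k2, aB1, mB1)
        h = 2.0 * (tt1 + tt2 + kappa)
        lo = yy - h
        hi = yy + h
        glo = _g_hoisted(lo, tt2, kind, k2, aA1, mA1, vA1, aB1, mB1, vB1,
                         mu_a, logw_a, mu_b, logw_b, aw2, mw2, bw2, mb2)
        ghi = _g_hoisted(hi, tt2, kind, k2, aA1, mA1, vA1, aB1, mB1, vB1,
                         mu_a, logw_a, mu_b, logw_b, aw2, mw2, bw2, mb2)
        for _ in range(8):
            if glo > 0.0 and ghi < 0.0:
                break
            h *= 2.0
            if glo <= 0.0:
                lo = yy - h
                glo = _g_hoisted(lo, tt2, kind, k2, aA1, mA1, vA1, aB1,
                                 mB1, vB1, mu_a, logw_a, mu_b, logw_b,
                                 aw2, mw2, bw2, mb2)
            if ghi >= 0.0:
                hi = yy + h
                ghi = _g_hoisted(hi, tt2, kind, k2, aA1, mA1, vA1, aB1,
                                 mB1, vB1, mu_a, logw_a, mu_b, logw_b,
                                 aw2, mw2, bw2, mb2)
        if not (glo > 0.0 and ghi < 0.0):
            gm = _g_hoisted(0.5 * (lo + hi), tt2, kind, k2, aA1, mA1, vA1,
                            aB1, mB1, vB1, mu_a, logw_a, mu_b, logw_b,
                            aw2, mw2, bw2, mb2)
            if gm < 0.0:
                roots[i] = -np.inf
                status[i] = -1
            else:
                roots[i] = np.inf
                status[i] = 1
            continue
        if do_scan:
            prev = glo
            for s in range(1, n_scan):
                x = lo + (hi - lo) * s / (n_scan - 1.0)
                val = _g_hoisted(x, tt2, kind, k2, aA1, mA1, vA1, aB1, mB1,
                                 vB1, mu_a, logw_a, mu_b, logw_b,
                                 aw2, mw2, bw2, mb2)
                if val - prev > 1e-9:
                    n_nonmono += 1
                    break
                prev = val
        side = 0
        for it in range(200):
            if it % 4 == 3 or ghi == glo:
                x = 0.5 * (lo + hi)
            else:
                x = hi - ghi * (hi - lo) / (ghi - glo)
                margin = 0.01 * (hi - lo)
                if x < lo + margin:
                    x = lo + margin
                elif x > hi - margin:
                    x = hi - margin
            gx = _g_hoisted(x, tt2, kind, k2, aA1, mA1, vA1, aB1, mB1, vB1,
                            mu_a, logw_a, mu_b, logw_b, aw2, mw2, bw2, mb2)
            if gx > 0.0:
                lo = x
                glo = gx
                if side == 1:
                    ghi *= 0.5
                side = 1
            else:
                hi = x
                ghi = gx
                if side == -1:
                    glo *= 0.5
                side = -1
            if hi - lo < xtol:
                break
        roots[i] = 0.5 * (lo + hi)
    return roots, status, n_nonmono
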