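"""Compiled hot loops for the penalized-KS estimator.

The full estimation scans ~30 Box-Cox lambda values x up to 1,600 truncation
candidates, running a 2-parameter Nelder-Mead fit per candidate; each
objective evaluation touches every distinct histogram value.  These loops are
JIT-compiled with numba.  The standard-normal CDF is read from a dense lookup
table with linear interpolation (absolute error < 1e-8 at the chosen grid);
the publicly documented objective in :mod:`ksref.estimator` uses the exact
``scipy.special.ndtr`` and is the reference the kernel is tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import ndtr

# Lookup table for the standard normal CDF on [-10, 10].  Linear interpolation
# error is bounded by h^2/8 * max|phi'| ~ 7e-9 at 2048 steps per unit.
_PHI_XMAX = 10.0
_PHI_SPU = 2048.0
PHI_TABLE = ndtr(np.linspace(-_PHI_XMAX, _PHI_XMAX, int(2 * _PHI_XMAX * _PHI_SPU) + 1))
PHI_TABLE.flags.writeable = False

BIG = 1e300  # sentinel for degenerate configurations (sigma <= 0, q ~ 0)
TIE_TOL = 1e-12  # objective totals closer than this are treated as tied


@njit(cache=True, nogil=True, inline="always")
def _phi(x, table):
    if x <= -10.0:
        return 0.0
    if x >= 10.0:
        return 1.0
    t = (x + 10.0) * 2048.0
    i = int(t)
    f = t - i
    return table[i] + (table[i + 1] - table[i]) * f


@njit(cache=True, nogil=True)
def _objective_idx(eu, el, cum, n_total, i1, i2, mu, sigma, table):
    """Penalized KS total for the truncation bins [i1, i2] at (mu, sigma).

    ``eu``/``el`` are the transformed upper/lower bin edges of the distinct
    rounded values; the ECDF at a rounded value carries the continuum mass up
    to its upper edge, so the Gaussian CDF is evaluated at upper edges and the
    truncation interval is anchored at the lower edge of its first bin.
    Inside the interval the conditional (renormalized) ECDF is compared with
    the conditional Gaussian CDF; outside it, the scaled physiological CDF may
    not exceed the observed cumulative mass below T (p1) nor may the scaled
    physiological survival exceed the observed survival above T (p2).
    """
    if sigma <= 0.0 or not np.isfinite(mu) or not np.isfinite(sigma):
        return BIG
    inv = 1.0 / sigma
    p_lo = _phi((el[i1] - mu) * inv, table)
    p_hi = _phi((eu[i2] - mu) * inv, table)
    q = p_hi - p_lo
    if q < 1e-6:
        return BIG
    base = cum[i1 - 1] if i1 > 0 else 0.0
    n_in = cum[i2] - base
    if n_in <= 0.0:
        return BIG
    c = (n_in / n_total) / q

    ks = 0.0
    for i in range(i1, i2 + 1):
        f_t = (_phi((eu[i] - mu) * inv, table) - p_lo) / q
        d = (cum[i] - base) / n_in - f_t
        if d < 0.0:
            d = -d
        if d > ks:
            ks = d

    p1 = 0.0
    for i in range(i1):
        v = c * _phi((eu[i] - mu) * inv, table) - cum[i] / n_total
        if v > p1:
            p1 = v

    p2 = 0.0
    n = eu.shape[0]
    for i in range(i2 + 1, n):
        v = cum[i] / n_total - (1.0 - c * (1.0 - _phi((eu[i] - mu) * inv, table)))
        if v > p2:
            p2 = v

    return (ks + p1 + p2) / np.sqrt(n_in)


@njit(cache=True, nogil=True)
def _weighted_quantile(zs, cum, i1, i2, frac):
    """Value at cumulative fraction ``frac`` of the histogram slice [i1, i2]."""
    base = cum[i1 - 1] if i1 > 0 else 0.0
    n_in = cum[i2] - base
    target = base + frac * n_in
    lo = i1
    hi = i2
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] >= target:
            hi = mid
        else:
            lo = mid + 1
    return zs[lo]


@njit(cache=True, nogil=True)
def _weighted_mean_sd(zs, counts, cum, i1, i2):
    base = cum[i1 - 1] if i1 > 0 else 0.0
    n_in = cum[i2] - base
    m = 0.0
    for i in range(i1, i2 + 1):
        m += counts[i] * zs[i]
    m /= n_in
    v = 0.0
    for i in range(i1, i2 + 1):
        d = zs[i] - m
        v += counts[i] * d * d
    if n_in > 1.0:
        v /= n_in - 1.0
    return m, np.sqrt(v)


@njit(cache=True, nogil=True)
def _nelder_mead(eu, el, cum, n_total, i1, i2, x0m, x0s, tol, maxiter, table):
    """Minimize the objective over (mu, sigma); standard Nelder-Mead.

    Coefficients: reflection 1, expansion 2, contraction 0.5, shrink 0.5.
    Terminates when the spread of simplex function values is below ``tol``
    or after ``maxiter`` iterations.  Returns (mu, sigma, f, converged).
    """
    sm = np.empty(3)
    ss = np.empty(3)
    fv = np.empty(3)
    dm = 0.05 * abs(x0m)
    if dm < 0.05 * x0s:
        dm = 0.05 * x0s
    if dm <= 0.0:
        dm = 2.5e-4
    ds = 0.05 * x0s
    if ds <= 0.0:
        ds = 2.5e-4
    sm[0], ss[0] = x0m, x0s
    sm[1], ss[1] = x0m + dm, x0s
    sm[2], ss[2] = x0m, x0s + ds
    for k in range(3):
        fv[k] = _objective_idx(eu, el, cum, n_total, i1, i2, sm[k], ss[k], table)

    converged = False
    for _ in range(maxiter):
        # order the three vertices (stable: lower index wins ties)
        o0, o1, o2 = 0, 1, 2
        if fv[o1] < fv[o0]:
            o0, o1 = o1, o0
        if fv[o2] < fv[o1]:
            o1, o2 = o2, o1
            if fv[o1] < fv[o0]:
                o0, o1 = o1, o0
        if fv[o2] - fv[o0] <= tol:
            converged = True
            break

        cm = 0.5 * (sm[o0] + sm[o1])
        cs = 0.5 * (ss[o0] + ss[o1])
        # reflection
        rm = cm + (cm - sm[o2])
        rs = cs + (cs - ss[o2])
        fr = _objective_idx(eu, el, cum, n_total, i1, i2, rm, rs, table)
        if fr < fv[o0]:
            # expansion
            em = cm + 2.0 * (cm - sm[o2])
            es = cs + 2.0 * (cs - ss[o2])
            fe = _objective_idx(eu, el, cum, n_total, i1, i2, em, es, table)
            if fe < fr:
                sm[o2], ss[o2], fv[o2] = em, es, fe
            else:
                sm[o2], ss[o2], fv[o2] = rm, rs, fr
        elif fr < fv[o1]:
            sm[o2], ss[o2], fv[o2] = rm, rs, fr
        else:
            if fr < fv[o2]:
                # outside contraction
                km = cm + 0.5 * (rm - cm)
                ks_ = cs + 0.5 * (rs - cs)
            else:
                # inside contraction
                km = cm - 0.5 * (cm - sm[o2])
                ks_ = cs - 0.5 * (cs - ss[o2])
            fk = _objective_idx(eu, el, cum, n_total, i1, i2, km, ks_, table)
            if fk < min(fr, fv[o2]):
                sm[o2], ss[o2], fv[o2] = km, ks_, fk
            else:
                # shrink toward the best vertex
                for k in range(3):
                    if k != o0:
                        sm[k] = sm[o0] + 0.5 * (sm[k] - sm[o0])
                        ss[k] = ss[o0] + 0.5 * (ss[k] - ss[o0])
                        fv[k] = _objective_idx(
                            eu, el, cum, n_total, i1, i2, sm[k], ss[k], table
                        )

    b = 0
    if fv[1] < fv[b]:
        b = 1
    if fv[2] < fv[b]:
        b = 2
    return sm[b], ss[b], fv[b], converged


@njit(cache=True, nogil=True)
def _fit_candidate(
    eu, el, counts, cum, n_total, i1, i2, tol, maxiter, warm_m, warm_s, use_warm, table
):
    """One (mu, sigma) fit for a single truncation candidate.

    Starts from the robust initializer (median, IQR/1.349 inside T); an
    optional warm start from a neighbouring candidate's optimum is used when
    it evaluates better.  If the first run hits the iteration cap, one
    restart from (mean, SD) inside T is attempted and the better result kept.
    """
    m0 = _weighted_quantile(eu, cum, i1, i2, 0.5)
    s0 = (
        _weighted_quantile(eu, cum, i1, i2, 0.75)
        - _weighted_quantile(eu, cum, i1, i2, 0.25)
    ) / 1.349
    wm, ws = _weighted_mean_sd(eu, counts, cum, i1, i2)
    if s0 <= 0.0:
        s0 = ws
    if s0 <= 0.0:
        s0 = 0.25 * (eu[i2] - eu[i1])
    if s0 <= 0.0:
        s0 = 1e-3

    if use_warm and warm_s > 0.0:
        f_warm = _objective_idx(eu, el, cum, n_total, i1, i2, warm_m, warm_s, table)
        f_rob = _objective_idx(eu, el, cum, n_total, i1, i2, m0, s0, table)
        if f_warm < f_rob:
            m0, s0 = warm_m, warm_s

    mu, sig, f, conv = _nelder_mead(
        eu, el, cum, n_total, i1, i2, m0, s0, tol, maxiter, table
    )
    if not conv:
        rs = ws if ws > 0.0 else s0
        mu2, sig2, f2, _ = _nelder_mead(
            eu, el, cum, n_total, i1, i2, wm, rs, tol, maxiter, table
        )
        if f2 < f:
            mu, sig, f = mu2, sig2, f2
    return mu, sig, f


@njit(cache=True, nogil=True)
def _scan_candidates(eu, el, counts, cum, n_total, c1, c2, tol, maxiter, use_warm, table):
    """Fit every truncation candidate at a fixed lambda; return the best.

    Ties within TIE_TOL on the objective prefer the wider interval (larger
    n_inside).  Candidates are visited in a fixed order so warm-starting does
    not affect determinism.  Returns (f, mu, sigma, candidate_index).
    """
    best_f = BIG
    best_m = 0.0
    best_s = -1.0
    best_n = -1.0
    best_j = -1
    warm_m = 0.0
    warm_s = -1.0
    for j in range(c1.shape[0]):
        i1 = c1[j]
        i2 = c2[j]
        mu, sig, f = _fit_candidate(
            eu, el, counts, cum, n_total, i1, i2, tol, maxiter, warm_m, warm_s, use_warm, table
        )
        warm_m, warm_s = mu, sig
        if f >= BIG:
            continue
        base = cum[i1 - 1] if i1 > 0 else 0.0
        n_in = cum[i2] - base
        if f < best_f - TIE_TOL:
            best_f, best_m, best_s, best_n, best_j = f, mu, sig, n_in, j
        elif f <= best_f + TIE_TOL and n_in > best_n:
            best_f, best_m, best_s, best_n, best_j = f, mu, sig, n_in, j
    return best_f, best_m, best_s, best_j
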