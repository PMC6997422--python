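"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and scipy.stats.norm, on
purpose: no shared code paths with the package internals.
"""

import math

from scipy.stats import norm


def oracle_boxcox(x: float, lam: float) -> float:
    if lam == 0.0:
        return math.log(x)
    # expm1 form: numerically stable for small lam (the naive power formula
    # collapses to 0/lam at float precision)
    return math.expm1(lam * math.log(x)) / lam


def oracle_objective(values, decimals, lam, mu, sigma, t1, t2):
    """Penalized-KS breakdown by direct triple loop over distinct values.

    Bin-edge convention: a value rounded to k covers [k - h/2, k + h/2), so
    the Gaussian CDF is compared at transformed upper bin edges, and the
    truncation interval is anchored at the lower edge of its first bin.
    Returns (ks_main, p1, p2), each already divided by sqrt(n_inside).
    """
    h = 10.0 ** (-decimals)
    rounded = [round(v, decimals) for v in values]
    distinct = sorted(set(rounded))
    counts = [sum(1 for r in rounded if r == d) for d in distinct]
    n_total = len(rounded)
    cum = []
    run = 0
    for c in counts:
        run += c
        cum.append(run)

    centers = [oracle_boxcox(d, lam) for d in distinct]
    upper = [oracle_boxcox(d + 0.5 * h, lam) for d in distinct]
    lower = [oracle_boxcox(d - 0.5 * h, lam) for d in distinct]

    inside = [i for i, c in enumerate(centers) if t1 <= c <= t2]
    if not inside:
        return (float("inf"), 0.0, 0.0)
    i1, i2 = inside[0], inside[-1]
    base = cum[i1 - 1] if i1 > 0 else 0
    n_in = cum[i2] - base
    p_lo = norm.cdf(lower[i1], loc=mu, scale=sigma)
    p_hi = norm.cdf(upper[i2], loc=mu, scale=sigma)
    q = p_hi - p_lo
    if q < 1e-6 or n_in <= 0:
        return (float("inf"), 0.0, 0.0)
    c_frac = (n_in / n_total) / q
    sq = math.sqrt(n_in)

    ks = 0.0
    for i in range(i1, i2 + 1):
        f_t = (norm.cdf(upper[i], loc=mu, scale=sigma) - p_lo) / q
        d_t = (cum[i] - base) / n_in
        ks = max(ks, abs(d_t - f_t))

    p1 = 0.0
    for i in range(i1):
        p1 = max(p1, c_frac * norm.cdf(upper[i], loc=mu, scale=sigma) - cum[i] / n_total)

    p2 = 0.0
    for i in range(i2 + 1, len(distinct)):
        surv = 1.0 - c_frac * (1.0 - norm.cdf(upper[i], loc=mu, scale=sigma))
        p2 = max(p2, cum[i] / n_total - surv)

    return (ks / sq, p1 / sq, p2 / sq)


def oracle_quantile(sorted_values, q):
    """Linear-interpolation quantile on a pre-sorted list (index rule (n-1)q)."""
    n = len(sorted_values)
    pos = (n - 1) * q
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_values[lo] * (1.0 - frac) + sorted_values[hi] * frac


def oracle_ecdf(values, decimals, lam, x):
    """Counting ECDF: fraction of rounded values whose transform is <= x."""
    rounded = [round(v, decimals) for v in values]
    return sum(1 for r in rounded if oracle_boxcox(r, lam) <= x) / len(rounded)
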