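"""First-principles statistical procedures used throughout the pipeline.

This module implements, from scratch, the statistics the analysis depends
on: Hartigan & Hartigan's dip statistic for unimodality (with a seeded
uniform-bootstrap p-value), the exact two-tailed binomial test (small-
p-values convention), Pearson and Spearman correlation with t-based
two-sided p-values, Deming errors-in-variables regression, and the
two-sample Kolmogorov-Smirnov statistic (exact path-count p-value for
small samples, asymptotic series otherwise).

Only distribution primitives (the binomial PMF, the t CDF) come from
scipy.special; the procedures themselves are implemented here so that
their conventions are explicit and testable against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, exp, log, sqrt

import numpy as np
from scipy import special

__all__ = [
    "DipResult",
    "DemingFit",
    "dip_statistic",
    "dip_test",
    "binomial_two_tailed",
    "pearson",
    "spearman",
    "deming_fit",
    "ks_two_sample",
]


# --------------------------------------------------------------------------
# Hartigan's dip
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its bootstrap p-value."""

    dip: float
    p_value: float
    n: int
    n_boot: int
    seed: int


def dip_statistic(sample) -> float:
    """Hartigan & Hartigan's dip statistic of a 1-D sample.

    The dip is the smallest sup-norm distance between the empirical CDF
    and any unimodal CDF.  Computed with the greatest-convex-minorant /
    least-concave-majorant algorithm: the modal interval is shrunk
    iteratively while tracking the largest deviation of the ECDF from
    the best convex fit below the mode and concave fit above it.

    Parameters
    ----------
    sample : array-like
        At least 4 finite values.

    Returns
    -------
    float
        The dip, in ``[0, 0.25]``; at least ``1/(2n)`` for non-degenerate
        samples.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = int(x.size)
    if n < 4:
        raise ValueError(f"dip statistic requires n >= 4, got n={n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    if x[0] == x[-1]:
        # Point mass: the ECDF is itself a (degenerate) unimodal CDF.
        return 0.0

    low, high = 0, n - 1
    dip = 1.0  # in count units; divided by 2n on return

    # mn[j]: leftmost index combined with j in the convex-minorant fit.
    mn = np.empty(n, dtype=np.int64)
    mn[low] = low
    for j in range(low + 1, high + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == low or (x[j] - x[mnj]) * (mnj - mnmnj) < (
                x[mnj] - x[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj
    # mj[j]: rightmost index combined with j in the concave-majorant fit.
    mj = np.empty(n, dtype=np.int64)
    mj[high] = high
    for j in range(high - 1, low - 1, -1):
        mj[j] = j + 1
        while True:
            mjj = mj[j]
            mjmjj = mj[mjj]
            if mjj == high or (x[j] - x[mjj]) * (mjj - mjmjj) < (
                x[mjj] - x[mjmjj]
            ) * (j - mjj):
                break
            mj[j] = mjmjj

    while True:
        # Change points of the GCM (high -> low) and LCM (low -> high),
        # 1-indexed to keep the classic formulation intact.
        gcm = [0, high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm) - 1
        ig = l_gcm
        ix = ig - 1

        lcm = [0, low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm) - 1
        ih = l_lcm
        iv = 2

        # Largest distance between the GCM and LCM on [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # Dip inside the current modal-interval candidates.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                jj = np.arange(jb, je + 1)
                t = float(np.max((jj - jb + 1) - (x[jj] - x[jb]) * c))
                dip_l = max(dip_l, t)
            else:
                dip_l = max(dip_l, 1.0)
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                jj = np.arange(jb, je + 1)
                t = float(np.max((x[jj] - x[jb]) * c - (jj - jb - 1)))
                dip_u = max(dip_u, t)
            else:
                dip_u = max(dip_u, 1.0)

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


# Null dip distributions are a function of (n, n_boot, seed) only, so they
# are cached: calibration suites re-test many observed samples against one
# reference null sample.
_DIP_NULL_CACHE: dict = {}


def _dip_null(n: int, n_boot: int, seed: int) -> np.ndarray:
    key = (n, n_boot, seed)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = dip_statistic(rng.uniform(0.0, 1.0, size=n))
        _DIP_NULL_CACHE[key] = boots
    return _DIP_NULL_CACHE[key]


def dip_test(sample, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Dip test of unimodality with a uniform-bootstrap null.

    The p-value is the fraction of ``n_boot`` uniform(0, 1) samples of
    the same size whose dip is at least the observed dip (the uniform is
    the asymptotically least favourable unimodal null).

    Returns a :class:`DipResult`; ``p_value`` resolution is ``1/n_boot``.
    """
    x = np.asarray(sample, dtype=float)
    d = dip_statistic(x)
    boots = _dip_null(int(x.size), int(n_boot), int(seed))
    p = float(np.mean(boots >= d))
    return DipResult(dip=d, p_value=p, n=int(x.size), n_boot=int(n_boot), seed=int(seed))


# --------------------------------------------------------------------------
# Exact binomial test
# --------------------------------------------------------------------------

def _binom_pmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    # Stable log-space PMF; exact enough for the <= comparison below.
    k = np.asarray(k)
    with np.errstate(divide="ignore"):
        logpmf = (
            special.gammaln(n + 1)
            - special.gammaln(k + 1)
            - special.gammaln(n - k + 1)
            + np.where(k > 0, k * np.log(p), 0.0)
            + np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
        )
    return np.exp(logpmf)


def binomial_two_tailed(k: int, n: int, p0: float, method: str = "small-p") -> float:
    """Exact two-tailed binomial test of ``k`` successes in ``n`` trials.

    ``method="small-p"`` (default) sums ``P(X = i)`` over every outcome
    whose point probability does not exceed ``P(X = k)`` (with a small
    relative tolerance for floating-point ties).  ``method="double"``
    doubles the smaller one-sided tail, capped at 1.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"need 0 < p0 < 1, got p0={p0}")
    i = np.arange(n + 1)
    pmf = _binom_pmf(i, n, p0)
    if method == "small-p":
        p = float(np.sum(pmf[pmf <= pmf[k] * (1.0 + 1e-7)]))
    elif method == "double":
        lower = float(np.sum(pmf[: k + 1]))
        upper = float(np.sum(pmf[k:]))
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(p, 1.0)


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------

def _t_two_sided_p(t: float, df: int) -> float:
    return float(2.0 * special.stdtr(df, -abs(t)))


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("pearson requires paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pearson requires finite values")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("pearson undefined for zero-variance input")
    r = float(np.dot(dx, dy) / sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * sqrt((n - 2) / (1.0 - r * r))
    return r, _t_two_sided_p(t, n - 2)


def _average_ranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pearson(_average_ranks(x), _average_ranks(y))


# --------------------------------------------------------------------------
# Deming regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DemingFit:
    """Errors-in-variables straight-line fit.

    ``lam`` weights the squared x-residuals relative to the squared
    y-residuals in the minimized loss ``sum((y - yhat)^2 + lam*(x - xhat)^2)``;
    ``lam = 1`` is orthogonal regression, ``lam -> inf`` approaches
    ordinary least squares of y on x.
    """

    slope: float
    intercept: float
    lam: float


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Closed-form Deming regression of ``y`` on ``x``.

    Minimizes ``sum_i (y_i - eta_i)^2 + lam * (x_i - xi_i)^2`` over points
    ``(xi_i, eta_i)`` constrained to a line.  With ``lam = 1`` the fit is
    symmetric under exchanging the axes (slope maps to its reciprocal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("deming_fit requires paired samples with n >= 3")
    if lam <= 0:
        raise ValueError("lam must be positive")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx)) / n
    syy = float(np.dot(dy, dy)) / n
    sxy = float(np.dot(dx, dy)) / n
    if sxx == 0.0 and syy == 0.0:
        raise ValueError("deming_fit undefined for degenerate (all-identical) input")
    if sxy == 0.0:
        # Principal axis is vertical or horizontal; pick the flatter line.
        slope = 0.0 if syy <= lam * sxx else float("inf")
    else:
        slope = (syy - lam * sxx + sqrt((syy - lam * sxx) ** 2 + 4.0 * lam * sxy**2)) / (
            2.0 * sxy
        )
    intercept = float(y.mean() - slope * x.mean()) if np.isfinite(slope) else float("nan")
    return DemingFit(slope=float(slope), intercept=intercept, lam=float(lam))


# --------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov
# --------------------------------------------------------------------------

def _ks_asymptotic_p(d: float, m: int, n: int) -> float:
    en = sqrt(m * n / (m + n))
    lam = (en + 0.12 + 0.11 / en) * d
    if lam <= 0:
        return 1.0
    terms = [2.0 * (-1.0) ** (k - 1) * exp(-2.0 * k * k * lam * lam) for k in range(1, 101)]
    return float(min(1.0, max(0.0, sum(terms))))


def _ks_exact_p(d: float, m: int, n: int) -> float:
    """P(D >= d) under the permutation null by lattice-path counting.

    Counts monotone paths from (0, 0) to (m, n) that stay strictly within
    ``|i/m - j/n| < d``; valid when the pooled sample has no ties.
    """
    eps = 1e-12
    counts = np.zeros((m + 1, n + 1), dtype=float)
    counts[0, 0] = 1.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            if abs(i / m - j / n) >= d - eps:
                counts[i, j] = 0.0
                continue
            c = 0.0
            if i > 0:
                c += counts[i - 1, j]
            if j > 0:
                c += counts[i, j - 1]
            counts[i, j] = c
    total = comb(m + n, m)
    return float(1.0 - counts[m, n] / total)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS statistic ``D = sup |ECDF_a - ECDF_b|`` and p-value.

    Uses exact lattice-path enumeration when ``min(len(a), len(b)) <= 10``
    and the pooled sample is tie-free; otherwise the asymptotic series.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    m, n = a.size, b.size
    if m == 0 or n == 0:
        raise ValueError("ks_two_sample requires nonempty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / m
    cdf_b = np.searchsorted(b, pooled, side="right") / n
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    if min(m, n) <= 10 and np.unique(pooled).size == pooled.size:
        p = _ks_exact_p(d, m, n)
    else:
        p = _ks_asymptotic_p(d, m, n)
    return d, p
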