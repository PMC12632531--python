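"""Independent brute-force oracles used to validate the implementations.

Each oracle recomputes a quantity by direct search/enumeration, sharing
no code path with the implementation it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.optimize import linprog, minimize


def lp_dip(sample) -> float:
    """Dip by direct minimization: the smallest sup-distance between the
    ECDF and any piecewise-linear unimodal CDF (atom allowed at the
    mode), via one linear program per candidate mode position."""
    x = np.sort(np.asarray(sample, float))
    n = x.size
    uniq = np.unique(x)
    span = max(1.0, uniq[-1] - uniq[0])
    grid = [uniq[0] - 1000.0 * span]
    for i, v in enumerate(uniq):
        grid.append(v)
        if i + 1 < len(uniq):
            grid.append(0.5 * (v + uniq[i + 1]))
    grid.append(uniq[-1] + 1000.0 * span)
    grid = np.array(grid)
    m = grid.size
    sample_idx = {}
    for v in uniq:
        idx = int(np.where(grid == v)[0][0])
        i_lo = int(np.searchsorted(x, v, side="left")) + 1
        i_hi = int(np.searchsorted(x, v, side="right"))
        sample_idx[idx] = (i_lo, i_hi)
    best = np.inf
    for k in range(m):
        # variables: g_0..g_{m-1} (left-limit values), g_jump (value at the
        # mode seen from the right, index m), d (index m+1)
        nv = m + 2
        A_ub, b_ub = [], []

        def row():
            return np.zeros(nv)

        for idx, (i_lo, i_hi) in sample_idx.items():
            tgt = m if idx == k else idx
            r = row(); r[tgt] = -1.0; r[m + 1] = -1.0
            A_ub.append(r); b_ub.append(-i_hi / n)          # right value >= i_hi/n - d
            r = row(); r[idx] = 1.0; r[m + 1] = -1.0
            A_ub.append(r); b_ub.append((i_lo - 1) / n)     # left value <= (i_lo-1)/n + d
        for j in range(m - 1):
            r = row(); r[j] = 1.0; r[j + 1] = -1.0
            A_ub.append(r); b_ub.append(0.0)
        r = row(); r[k] = 1.0; r[m] = -1.0
        A_ub.append(r); b_ub.append(0.0)
        if k + 1 < m:
            r = row(); r[m] = 1.0; r[k + 1] = -1.0
            A_ub.append(r); b_ub.append(0.0)

        def right_val(j):
            return m if j == k else j

        for j in range(1, m - 1):
            h1 = grid[j] - grid[j - 1]
            h2 = grid[j + 1] - grid[j]
            if j + 1 <= k:  # convex below the mode
                r = row()
                r[j + 1] += -h1; r[j] += h1 + h2; r[j - 1] += -h2
                A_ub.append(r); b_ub.append(0.0)
            if j - 1 >= k:  # concave above the mode
                r = row()
                r[j + 1] += h1; r[j] += -(h1 + h2); r[right_val(j - 1)] += h2
                A_ub.append(r); b_ub.append(0.0)
        A_eq = np.zeros((2, nv)); b_eq = [0.0, 1.0]
        A_eq[0, 0] = 1.0; A_eq[1, m - 1] = 1.0
        c = np.zeros(nv); c[m + 1] = 1.0
        bounds = [(0, 1)] * (m + 1) + [(0, 0.5)]
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return float(best)


def threshold_scan(sweep, spike_peak_index: int, sd_multiplier: float = 5.0):
    """Exhaustive sample-by-sample scan for the first second-derivative
    exceedance; returns the Vm there, or None."""
    vm = sweep.vm
    dt = 1.0 / sweep.sampling_rate
    d2 = np.zeros_like(vm)
    for i in range(1, vm.size - 1):
        d2[i] = (vm[i + 1] - 2.0 * vm[i] + vm[i - 1]) / dt**2
    pre = sweep.pre_stim_mask()
    sigma = float(np.std(d2[pre]))
    assert sigma > 0
    for i in range(vm.size):
        if sweep.time_s[i] <= sweep.stim_onset:
            continue
        if i > spike_peak_index:
            break
        if d2[i] > sd_multiplier * sigma:
            return float(vm[i])
    return None


def binomial_enumeration(k: int, n: int, p0: float) -> float:
    """Two-tailed exact binomial by full outcome enumeration."""
    pmf = [comb(n, i) * p0**i * (1.0 - p0) ** (n - i) for i in range(n + 1)]
    pk = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= pk * (1.0 + 1e-7)))


def deming_numeric(x, y, lam: float = 1.0):
    """Deming fit by numerical minimization of the weighted orthogonal
    sum of squares (profile over the latent x positions)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def loss(ab):
        a, b = ab
        return float(np.sum(lam * (y - a - b * x) ** 2 / (lam + b**2)))

    b0 = np.polyfit(x, y, 1)[0]
    a0 = y.mean() - b0 * x.mean()
    res = minimize(loss, [a0, b0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return float(res.x[1]), float(res.x[0])


def ks_d_scan(a, b) -> float:
    """KS statistic by evaluating both ECDFs at every pooled point."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    best = 0.0
    for v in np.concatenate([a, b]):
        fa = np.sum(a <= v) / a.size
        fb = np.sum(b <= v) / b.size
        best = max(best, abs(fa - fb))
    return float(best)


def kmeans_splits(values):
    """Best contiguous 2-partition by explicit SSE over every split."""
    s = np.sort(np.asarray(values, float))
    n = s.size
    best_k, best_sse = None, np.inf
    for k in range(1, n):
        sse = float(np.sum((s[:k] - s[:k].mean()) ** 2) + np.sum((s[k:] - s[k:].mean()) ** 2))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return best_k, float(s[:best_k].mean()), float(s[best_k:].mean())
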