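"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library routines they are checking: ranks are
built by explicit sorting, quantiles by the textbook linear-interpolation
formula, regression by closed-form sums, and the compartment-model
convolution by trapezoidal quadrature on an oversampled grid.
"""
from __future__ import annotations

import math

import numpy as np


def mean_ranks(x) -> np.ndarray:
    """1-based ranks with ties averaged, via explicit stable sort."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j < x.size and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = (i + 1 + j) / 2.0
        i = j
    return ranks


def spearman_brute(x, y) -> float:
    """Pearson correlation of mean ranks (textbook definition)."""
    rx = mean_ranks(x)
    ry = mean_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def quantile_linear(values, q) -> float:
    """Linear-interpolation (type 7) quantile on sorted data."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (v.size - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, v.size - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def ols_brute(x, y):
    """Closed-form OLS slope/intercept/R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 0.0
    return slope, intercept, float(r2)


def rank_decile_sizes(n, n_bins=10):
    base, extra = divmod(n, n_bins)
    return [base + 1] * extra + [base] * (n_bins - extra)


def tofts_numeric(ktrans, kep, aif, times_s, oversample=10, h=None):
    """Trapezoid convolution of the plasma curve with the exponential residue.

    By default the grid is ``oversample`` times finer than the output grid;
    passing ``h`` fixes the quadrature step instead (trapezoid error scales as
    ``h**2 * max(kep, m)**2``, so ``h`` must shrink for fast kinetics).
    """
    times_s = np.asarray(times_s, dtype=float)
    out = np.empty(times_s.size)
    if h is None:
        n_all = int(oversample * max(len(times_s), 200))
        grid = np.linspace(0.0, times_s.max(), n_all)
    for i, t in enumerate(times_s):
        tau = np.arange(0.0, t, h) if h is not None else grid[grid < t]
        tau = np.append(tau, t)
        integrand = aif.cp(tau) * np.exp(-kep * (t - tau))
        out[i] = ktrans * np.trapezoid(integrand, tau)
    return out


def t1_grid_search(signals, trs_ms, lo=50.0, hi=5000.0, n=200000):
    """Dense 1D grid search for the saturation-recovery T1 (S0 by lstsq)."""
    signals = np.asarray(signals, dtype=float)
    trs = np.asarray(trs_ms, dtype=float)
    grid = np.geomspace(lo, hi, n)
    best = (np.inf, lo, 0.0)
    for t1 in grid:
        f = 1.0 - np.exp(-trs / t1)
        s0 = float(np.linalg.lstsq(f[:, None], signals, rcond=None)[0][0])
        rss = float(np.sum((signals - s0 * f) ** 2))
        if rss < best[0]:
            best = (rss, t1, s0)
    return best[1], best[2]
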