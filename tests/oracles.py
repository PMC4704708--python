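"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package code it checks: exact rational arithmetic, brute-force enumeration,
1-D grid integration, closed forms.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


# -- pedigree kinship by recursive coefficient-of-kinship definition --------

def kinship_oracle(ped: dict):
    """Kinship coefficients by direct recursion on (id -> (sire, dam)).

    phi(i, i) = 0.5 (1 + phi(s_i, d_i)); phi(i, j) = 0.5 (phi(s_i, j) +
    phi(d_i, j)) for i not an ancestor of j (evaluated with the younger
    individual first).  The additive relationship is 2 phi.
    """
    ids = list(ped)
    order = {k: v for v, k in enumerate(ids)}  # assumed parents-first
    cache = {}

    def phi(a, b):
        if a is None or b is None:
            return Fraction(0)
        if order[a] < order[b]:
            a, b = b, a
        key = (a, b)
        if key in cache:
            return cache[key]
        s, d = ped[a]
        if a == b:
            val = Fraction(1, 2) * (1 + phi(s, d))
        else:
            val = Fraction(1, 2) * (phi(s, b) + phi(d, b))
        cache[key] = val
        return val

    n = len(ids)
    A = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            A[i, j] = float(2 * phi(a, b))
    return ids, A


# -- exact HWE probabilities with rational arithmetic -----------------------

def hwe_pvalue_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value via exact Fraction enumeration."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nb = 2 * n - na
    if na == 0 or nb == 0:
        return 1.0
    denom = comb(2 * n, na)
    probs = {}
    for h in range(na % 2, min(na, nb) + 1, 2):
        naa = (na - h) // 2
        nbb = n - naa - h
        if nbb < 0:
            continue
        ways = Fraction(
            comb(n, naa) * comb(n - naa, h) * 2**h, denom
        )
        probs[h] = ways
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


# -- 1-D grid integration of an unnormalized log density --------------------

def grid_cdf(log_density, grid: np.ndarray):
    """Normalized CDF on a grid by trapezoidal integration."""
    logf = np.array([log_density(x) for x in grid], dtype=float)
    logf -= logf.max()
    f = np.exp(logf)
    cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2.0
                                           * np.diff(grid))])
    return cdf / cdf[-1]


def ks_distance(draws: np.ndarray, log_density, grid: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance of draws to the grid-integrated CDF."""
    cdf = grid_cdf(log_density, grid)
    x = np.sort(np.asarray(draws, float))
    theo = np.interp(x, grid, cdf)
    emp_hi = np.arange(1, len(x) + 1) / len(x)
    emp_lo = np.arange(0, len(x)) / len(x)
    return float(max(np.max(np.abs(emp_hi - theo)),
                     np.max(np.abs(emp_lo - theo))))


def haldane_recombination(d: float) -> float:
    """Recombination fraction at map distance d under Poisson crossovers."""
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def loo_predictive_logpdf(y: np.ndarray, i: int, sigma2: float) -> float:
    """Closed-form leave-one-out predictive density for the
    known-variance normal model with a flat prior on the mean."""
    mask = np.ones(len(y), bool)
    mask[i] = False
    m = y[mask].mean()
    k = mask.sum()
    var = sigma2 * (1.0 + 1.0 / k)
    return float(-0.5 * (np.log(2 * np.pi * var) + (y[i] - m) ** 2 / var))
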