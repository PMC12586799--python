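"""Independent brute-force oracles used by the unit and acceptance tests.

These stay deliberately naive: exact rational arithmetic and explicit
enumeration, never sharing code with the implementation under test.
"""

from fractions import Fraction
from math import comb, factorial

import numpy as np


def hwe_enumeration_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> Fraction:
    """Exact HWE p by enumerating every genotype table with the observed
    allele counts and summing probabilities <= that of the observed table."""
    n = n_hom_major + n_het + n_hom_minor
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    tables = []
    for het in range(rare + 1):
        if (rare - het) % 2:
            continue
        hom_minor = (rare - het) // 2
        hom_major = n - het - hom_minor
        if hom_major < 0:
            continue
        weight = Fraction(factorial(n) * 2**het, factorial(hom_major) * factorial(het) * factorial(hom_minor))
        tables.append((het, weight))
    total = sum(wt for _, wt in tables)
    probs = {het: wt / total for het, wt in tables}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def hypergeom_enumeration_p(k: int, N: int, m: int, K: int) -> Fraction:
    """Upper-tail P(X >= k) by summing the exact count of qualifying draws."""
    total = comb(N, K)
    hits = sum(comb(m, j) * comb(N - m, K - j) for j in range(k, min(m, K) + 1))
    return Fraction(hits, total)


def bh_stepup_naive(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up, O(m^2): q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i in range(m):
        candidates = [min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_i, m)]
        q[order[rank_i]] = min(candidates)
    return q


def prs_double_loop(dosages: np.ndarray, weights: np.ndarray, mean_impute: bool = True) -> np.ndarray:
    """Per-sample, per-variant accumulation with explicit missing handling."""
    n, v = dosages.shape
    col_means = []
    for j in range(v):
        col = dosages[:, j]
        col_means.append(np.nanmean(col))
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(v):
            d = dosages[i, j]
            if np.isnan(d):
                if mean_impute:
                    d = col_means[j]
                else:
                    continue
            acc += weights[j] * d
        out[i] = acc
    return out


def delta_adj_r2_two_regressions(y, s, cov) -> float:
    """Percent-scale adjusted-R2 difference via statsmodels, independently."""
    import statsmodels.api as sm

    X_full = sm.add_constant(np.column_stack([s, cov]))
    X_cov = sm.add_constant(cov)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_cov).fit()
    return 100.0 * (full.rsquared_adj - red.rsquared_adj)
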