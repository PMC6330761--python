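"""Brute-force oracles, independent of the implementations they check."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def rank_sum_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of rank splits.

    All C(n_a+n_b, n_a) assignments of the pooled values to group A are
    enumerated; p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    idx = range(len(pooled))

    def u_stat(group_a_idx):
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in idx if i not in set(group_a_idx)]
        # count of (x, y) pairs with x > y plus half-ties
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in ga for y in gb
        )

    u_obs = u_stat(tuple(range(na)))
    us = [u_stat(c) for c in itertools.combinations(idx, na)]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def fisher_exact_enumerate(a, b, c, d) -> tuple[float, float]:
    """Two-sided Fisher p by enumerating all tables with the same margins.

    Probability-mass definition: sum the hypergeometric probabilities of
    every table whose probability does not exceed the observed one (with a
    small relative tolerance for float round-off).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        # hypergeometric point mass for table [[x, r1-x], [c1-x, r2-c1+x]]
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    p = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
    odds = float("inf") if b * c == 0 and a * d > 0 else (
        float("nan") if b * c == 0 else a * d / (b * c)
    )
    return odds, min(p, 1.0)


def pca_from_correlation(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the variables' correlation matrix.

    `matrix` is genes x samples. Returns (explained variance fractions,
    loadings as columns) sorted by decreasing eigenvalue.
    """
    x = matrix.T  # samples x variables
    corr = np.corrcoef(x, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    return vals / vals.sum(), vecs
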