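"""Nonparametric group comparisons and median expression profiles.

Two-group contrasts use the Wilcoxon-Mann-Whitney rank-sum test, three or
more groups the Kruskal-Wallis test, and 2x2 count tables Fisher's exact
test — the testing conventions behind every heat-map star annotation of the
analysis. Raw p-values are reported (no multiple-testing correction by
default, Benjamini-Hochberg available behind a flag) and mapped to the
figure star codes * (<0.05), ** (<0.01), *** (<0.001), **** (<0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "kruskal_wallis_test",
    "fisher_exact_test",
    "compare_profiles",
    "median_profile",
    "star_code",
    "ContingencyTable2x2",
]

#: Thresholds for the figure star convention, most stringent first.
_STAR_LEVELS: tuple[tuple[float, str], ...] = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


def star_code(p: float) -> str:
    """Map a p-value to the figure star convention (``ns`` if p >= 0.05)."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value out of (0, 1]: {p}")
    for threshold, stars in _STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Uses the exact null distribution when n_a + n_b <= 20 and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections. Returns ``(U, p)`` with U the statistic of the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), max(p, np.finfo(float).tiny)


def kruskal_wallis_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    Degenerate all-identical input returns H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("Kruskal-Wallis requires >=3 groups here; use rank_sum_test for 2")
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), min(float(p), 1.0)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Four non-negative counts; rows are one factor, columns the other."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table must have at least one positive count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_test(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    The odds ratio is the sample cross-product (a*d)/(b*c) — ``inf`` when
    b*c = 0 with a*d > 0, ``nan`` when both products vanish. The two-sided
    p-value sums hypergeometric probabilities of all same-margin tables
    whose probability does not exceed the observed one (probability-mass
    definition).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    arr = table.as_array()
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        oddsratio = float("inf") if ad > 0 else float("nan")
    else:
        oddsratio = ad / bc
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return oddsratio, min(float(p), 1.0)


def _select(annotation: pd.DataFrame, selector) -> pd.Index:
    """Resolve a sample selector: dict of column->value(s), list of ids, or callable."""
    if callable(selector):
        mask = annotation.apply(selector, axis=1).astype(bool)
        return annotation.index[mask]
    if isinstance(selector, Mapping):
        mask = pd.Series(True, index=annotation.index)
        for col, val in selector.items():
            if col not in annotation.columns:
                raise KeyError(f"annotation has no column {col!r}")
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            mask &= annotation[col].isin(list(allowed))
        return annotation.index[mask]
    return pd.Index(selector)


def compare_profiles(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    contrasts: Sequence[tuple],
    genes: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene rank-sum tests for a list of two-group contrasts.

    Each contrast is ``(label, selector_a, selector_b)`` where a selector is
    a dict of annotation-column filters (e.g. ``{"entity": "CLL"}``), an
    explicit sample-id list, or a callable over annotation rows. A contrast
    whose selector matches no sample yields per-contrast error rows rather
    than aborting the table. Raw p-values by default; `bh_correct` applies
    Benjamini-Hochberg within each contrast.
    """
    if genes is None:
        genes = list(matrix.index)
    frames = []
    for label, sel_a, sel_b in contrasts:
        ids_a = _select(annotation, sel_a)
        ids_b = _select(annotation, sel_b)
        if len(ids_a) == 0 or len(ids_b) == 0:
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "contrast": label,
                            "gene": "",
                            "error": "empty selector "
                            + ("A" if len(ids_a) == 0 else "B"),
                        }
                    ]
                )
            )
            continue
        rows = []
        for gene in genes:
            va = matrix.loc[gene, ids_a].to_numpy(dtype=float)
            vb = matrix.loc[gene, ids_b].to_numpy(dtype=float)
            u, p = rank_sum_test(va, vb)
            rows.append(
                {
                    "contrast": label,
                    "gene": gene,
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "statistic": u,
                    "p": p,
                }
            )
        sub = pd.DataFrame(rows)
        if bh_correct:
            sub["p_adj"] = multipletests(sub["p"], method="fdr_bh")[1]
            sub["stars"] = sub["p_adj"].map(star_code)
        else:
            sub["stars"] = sub["p"].map(star_code)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def median_profile(
    matrix: pd.DataFrame,
    grouping: pd.Series | Mapping[str, str],
    zscore: bool = False,
) -> pd.DataFrame:
    """Gene-by-group matrix of median expression, optionally row z-scored.

    Z-scoring centers and scales each gene row across groups (ddof=1); rows
    with zero spread across groups become all-zero.
    """
    if not isinstance(grouping, pd.Series):
        grouping = pd.Series(dict(grouping))
    grouping = grouping.loc[matrix.columns]
    if grouping.isna().any():
        raise ValueError("every sample needs a group label")
    med = matrix.T.groupby(grouping).median().T
    if zscore:
        mu = med.mean(axis=1)
        sd = med.std(axis=1, ddof=1)
        med = med.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return med
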