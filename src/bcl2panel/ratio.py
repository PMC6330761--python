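"""Venetoclax sensitivity ratios: scoring, candidate enumeration, ranking.

A candidate ratio divides the summed expression of genes promoting
venetoclax efficacy (BCL2, BCL2L11, BAX) by the summed expression of genes
mediating resistance (MCL1, BCL2L1, BCL2A1). Candidates are every
(non-empty efficacy subset) x (non-empty resistance subset) pair — 49 with
the default 3+3 pools — and are ranked by correlation of the per-sample (or
per-entity-median) score with entity-level overall response rates (ORR) to
venetoclax monotherapy.

Arithmetic is performed directly on the normalized log2 expression values,
the scale on which the pooled matrix lives; a linear-intensity option
(2**x before summing) is available via ``scale="linear"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bcl2panel import de

#: Genes whose expression promotes venetoclax-induced apoptosis.
EFFICACY_GENES: tuple[str, ...] = ("BCL2", "BCL2L11", "BAX")
#: Anti-apoptotic genes mediating venetoclax resistance.
RESISTANCE_GENES: tuple[str, ...] = ("MCL1", "BCL2L1", "BCL2A1")


@dataclass(frozen=True)
class RatioSpec:
    """Numerator/denominator gene sets defining a candidate sensitivity ratio."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError("numerator and denominator must be non-empty")
        object.__setattr__(self, "numerator", tuple(self.numerator))
        object.__setattr__(self, "denominator", tuple(self.denominator))

    def label(self) -> str:
        return "(%s)/(%s)" % ("+".join(self.numerator), "+".join(self.denominator))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.numerator) + tuple(self.denominator)


#: The ratio found to be the strongest predictor of venetoclax response.
SENSITIVITY_RATIO = RatioSpec(numerator=("BCL2", "BCL2L11", "BAX"), denominator=("BCL2L1",))


def _nonempty_subsets(pool: Sequence[str]) -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(pool) + 1):
        out.extend(itertools.combinations(pool, r))
    return out


def enumerate_ratio_specs(
    efficacy_pool: Sequence[str] = EFFICACY_GENES,
    resistance_pool: Sequence[str] = RESISTANCE_GENES,
) -> list[RatioSpec]:
    """All (non-empty efficacy subset) x (non-empty resistance subset) candidates.

    The order is deterministic: subsets by increasing size, then by pool
    order, numerator varying slowest. With the default 3+3 pools this yields
    (2**3 - 1)**2 = 49 candidates.
    """
    if not efficacy_pool or not resistance_pool:
        raise ValueError("gene pools must be non-empty")
    return [
        RatioSpec(num, den)
        for num in _nonempty_subsets(efficacy_pool)
        for den in _nonempty_subsets(resistance_pool)
    ]


def ratio_score(
    matrix: pd.DataFrame, spec: RatioSpec, scale: str = "log2"
) -> pd.Series:
    """Per-sample score: sum of numerator genes over sum of denominator genes.

    Parameters
    ----------
    matrix
        Gene-level expression, rows = genes, columns = samples, log2 scale.
    spec
        The ratio definition; all of its genes must be rows of `matrix`.
    scale
        ``"log2"`` (default) sums the log2 values as-is; ``"linear"``
        transforms to 2**x before summing.
    """
    missing = [g for g in spec.genes if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    if scale not in ("log2", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    vals = matrix.loc[list(spec.genes)]
    if scale == "linear":
        vals = np.power(2.0, vals)
    num = vals.loc[list(spec.numerator)].sum(axis=0)
    den = vals.loc[list(spec.denominator)].sum(axis=0)
    bad = den <= 0
    if bad.any():
        raise ValueError(
            "non-positive denominator sum for samples: "
            f"{list(den.index[bad])[:5]}"
        )
    score = num / den
    score.name = spec.label()
    return score


def rank_ratio_candidates(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    orr: Mapping[str, float],
    candidates: Iterable[RatioSpec] | None = None,
    summary: str = "per-sample",
    method: str = "pearson",
    scale: str = "log2",
) -> pd.DataFrame:
    """Rank candidate ratios by correlation with venetoclax ORR.

    Entities missing from `orr` are scored but excluded from the
    correlation. In ``per-sample`` mode every sample is paired with its
    entity's ORR; in ``median-per-entity`` mode one point per entity (the
    entity median score) enters the correlation.

    Returns a DataFrame sorted by decreasing r with columns
    ``rank, numerator, denominator, r, p, n``; ties in r are broken by
    candidate enumeration order.
    """
    if candidates is None:
        candidates = enumerate_ratio_specs()
    candidates = list(candidates)
    if summary not in ("per-sample", "median-per-entity"):
        raise ValueError(f"unknown summary mode {summary!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    entities = annotation["entity"]
    usable = entities[entities.isin([e for e, v in orr.items() if v is not None])]
    n_entities = usable.nunique()
    if n_entities < 3:
        raise ValueError(
            f"need >=3 entities with ORR values, found {n_entities}"
        )
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    rows = []
    for i, spec in enumerate(candidates):
        score = ratio_score(matrix, spec, scale=scale)
        score = score.loc[usable.index]
        if summary == "per-sample":
            x = score.to_numpy(dtype=float)
            y = usable.map(orr).to_numpy(dtype=float)
        else:
            med = score.groupby(usable).median()
            x = med.to_numpy(dtype=float)
            y = med.index.map(orr).to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError("fewer than 3 points for correlation")
        r, p = corr(x, y)
        rows.append(
            {
                "order": i,
                "numerator": "+".join(spec.numerator),
                "denominator": "+".join(spec.denominator),
                "r": float(r),
                "p": float(p),
                "n": int(x.size),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["r", "order"], ascending=[False, True], kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.drop(columns="order").reset_index(drop=True)[
        ["rank", "numerator", "denominator", "r", "p", "n"]
    ]


def candidate_rank(ranking: pd.DataFrame, spec: RatioSpec) -> int:
    """Rank (1 = best) of one candidate within a `rank_ratio_candidates` table."""
    mask = (ranking["numerator"] == "+".join(spec.numerator)) & (
        ranking["denominator"] == "+".join(spec.denominator)
    )
    if not mask.any():
        raise KeyError(f"candidate {spec.label()} not in ranking")
    return int(ranking.loc[mask, "rank"].iloc[0])


def compare_ratio_by_group(
    scores: pd.Series,
    annotation: pd.DataFrame,
    grouping: str,
) -> pd.DataFrame:
    """Pairwise rank-sum comparison of ratio scores between groups.

    `grouping` names an annotation column (``tissue``, ``subtype``,
    ``status`` or ``entity``); every unordered pair of groups is tested with
    a two-sided Wilcoxon-Mann-Whitney test and starred with the figure
    convention.
    """
    if grouping not in annotation.columns:
        raise KeyError(f"annotation has no column {grouping!r}")
    groups = annotation.loc[scores.index, grouping]
    levels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(levels) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for ga, gb in itertools.combinations(levels, 2):
        a = scores[groups == ga].to_numpy(dtype=float)
        b = scores[groups == gb].to_numpy(dtype=float)
        u, p = de.rank_sum_test(a, b)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": a.size,
                "n_b": b.size,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "U": u,
                "p": p,
                "stars": de.star_code(p),
            }
        )
    return pd.DataFrame(rows)
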