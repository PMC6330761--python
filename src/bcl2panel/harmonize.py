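"""Pooling multiple expression series into one comparable matrix.

Cross-series harmonization proceeds in three steps: quantile normalization
of the pooled matrix (every sample is forced onto the mean order-statistic
distribution), removal of outlier samples by median pairwise Spearman
correlation, and anchoring-gene QC — rank-sum checks that marker genes
(CCND1/SOX11 in MCL, CD38/SDC1 in MM, ...) are high where histology says
they must be, independent of source series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnchorRuleResult:
    gene: str
    entity: str
    p: float | None
    median_diff: float | None
    passed: bool
    error: str | None = None


@dataclass
class QCReport:
    """Outcome of anchoring-gene QC plus any flagged outlier samples."""

    rules: list[AnchorRuleResult] = field(default_factory=list)
    outliers: list[tuple[str, float]] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.rules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "entity": r.entity,
                    "p": r.p,
                    "median_diff": r.median_diff,
                    "passed": r.passed,
                    "error": r.error,
                }
                for r in self.rules
            ]
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "all_passed": self.all_passed,
            "rules": [vars(r) for r in self.rules],
            "outliers": [{"sample": s, "median_corr": c} for s, c in self.outliers],
        }


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-sample mean order-statistic vector.

    After normalization every sample has the identical sorted value vector.
    Tied values within a column receive the mean of the quantile values
    their rank block spans (mean-of-ranks convention). Row and column
    labels are preserved; requires at least two samples and finite values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the candidate quantile values within each tie block
        ser = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = ser.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _median_spearman(values: np.ndarray) -> np.ndarray:
    """Median Spearman correlation of each column with all the others."""
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    corr = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    return np.nanmedian(corr, axis=0)


def flag_outliers(matrix: pd.DataFrame, min_median_corr: float = 0.5) -> list[str]:
    """Samples whose median Spearman correlation with all others is below threshold.

    The criterion is scale-free and standard array-QC practice; the
    threshold is a tuning knob (default 0.5). Requires >=3 samples.
    """
    if matrix.shape[1] < 3:
        raise ValueError("outlier flagging needs >=3 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    med = _median_spearman(values)
    return [str(c) for c, m in zip(matrix.columns, med) if m < min_median_corr]


def outlier_report(matrix: pd.DataFrame, min_median_corr: float = 0.5) -> list[tuple[str, float]]:
    """Like `flag_outliers` but returns (sample, median correlation) pairs."""
    if matrix.shape[1] < 3:
        raise ValueError("outlier flagging needs >=3 samples")
    med = _median_spearman(matrix.to_numpy(dtype=float))
    return [
        (str(c), float(m))
        for c, m in zip(matrix.columns, med)
        if m < min_median_corr
    ]


def anchor_qc(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    rules: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> QCReport:
    """Check that each anchoring gene is high in its target entity.

    For each ``(gene, entity)`` rule a one-sided rank-sum test compares the
    gene's expression in the target entity against all other samples; the
    rule passes if p < alpha and the median difference is positive. A
    missing gene or entity yields a per-rule error entry, not a global
    failure.
    """
    report = QCReport(alpha=alpha)
    shared = matrix.columns.intersection(annotation.index)
    for gene, entity in rules:
        if gene not in matrix.index:
            report.rules.append(
                AnchorRuleResult(gene, entity, None, None, False, "gene missing")
            )
            continue
        in_entity = shared[annotation.loc[shared, "entity"] == entity]
        out_entity = shared[annotation.loc[shared, "entity"] != entity]
        if len(in_entity) == 0 or len(out_entity) == 0:
            report.rules.append(
                AnchorRuleResult(gene, entity, None, None, False, "entity missing")
            )
            continue
        va = matrix.loc[gene, in_entity].to_numpy(dtype=float)
        vb = matrix.loc[gene, out_entity].to_numpy(dtype=float)
        res = stats.mannwhitneyu(va, vb, alternative="greater")
        diff = float(np.median(va) - np.median(vb))
        passed = bool(res.pvalue < alpha and diff > 0)
        report.rules.append(
            AnchorRuleResult(gene, entity, float(res.pvalue), diff, passed)
        )
    return report
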