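"""Random-forest entity classification and transformation scoring.

A forest (1,000 trees by default) is trained to predict the malignant
entity from the 12-gene BCL2-family profile, then applied to FL and MALT
samples: if transformed (aggressive) cases are systematically re-labeled
DLBCL while indolent cases keep their diagnosis, the predicted-DLBCL x
aggressive-status 2x2 table has a large odds ratio — the quantitative
trace of histologic transformation in the expression panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from bcl2panel.de import ContingencyTable2x2, fisher_exact_test


@dataclass
class EntityClassifier:
    """A fitted forest plus the feature/gene order it expects."""

    model: RandomForestClassifier
    features: list[str]
    seed: int
    n_trees: int

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        missing = [g for g in self.features if g not in matrix.index]
        if missing:
            raise KeyError(f"matrix lacks classifier features: {missing}")
        x = matrix.loc[self.features].T.to_numpy(dtype=float)
        return pd.Series(self.model.predict(x), index=matrix.columns, name="predicted")


@dataclass
class ClassifierReport:
    """Transformation analysis: predictions, 2x2 table, odds ratio, Fisher p."""

    predictions: pd.Series
    confusion: pd.DataFrame
    table: ContingencyTable2x2
    odds_ratio: float
    p: float
    seed: int
    n_trees: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "p": self.p,
            "table": {
                "aggressive_predicted_dlbcl": self.table.a,
                "aggressive_predicted_other": self.table.b,
                "indolent_predicted_dlbcl": self.table.c,
                "indolent_predicted_other": self.table.d,
            },
            "seed": self.seed,
            "n_trees": self.n_trees,
            "params": self.params,
        }


def train_entity_classifier(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
    exclude_samples=(),
    features=None,
) -> EntityClassifier:
    """Fit a random forest predicting entity from the gene panel.

    `exclude_samples` removes held-out samples (typically the transformed
    FL/MALT cases under evaluation) from training. Deterministic given the
    seed; tree hyperparameters beyond the count follow the scikit-learn
    defaults and are recorded in the report.
    """
    features = list(features) if features is not None else list(matrix.index)
    keep = matrix.columns.difference(pd.Index(exclude_samples))
    if len(keep) == 0:
        raise ValueError("no training samples left after exclusion")
    y = annotation.loc[keep, "entity"]
    if y.nunique() < 2:
        raise ValueError("training set must contain >=2 entities")
    x = matrix.loc[features, keep].T.to_numpy(dtype=float)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(x, y.to_numpy())
    return EntityClassifier(model=model, features=features, seed=seed, n_trees=n_trees)


def score_transformation(
    clf: EntityClassifier,
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    target_entity: str = "DLBCL",
) -> ClassifierReport:
    """Predict entities for FL/MALT samples and test transformation recovery.

    Builds the 2x2 table (status aggressive?) x (predicted DLBCL?) over the
    evaluated samples; odds ratio is the sample cross-product with the
    infinite-OR convention on a zero margin, p from Fisher's exact test.
    """
    status = annotation.loc[matrix.columns, "status"]
    if not (status == "aggressive").any():
        raise ValueError("no aggressive samples to evaluate")
    pred = clf.predict(matrix)
    is_dlbcl = pred == target_entity
    is_aggr = status == "aggressive"
    a = int((is_aggr & is_dlbcl).sum())
    b = int((is_aggr & ~is_dlbcl).sum())
    c = int((~is_aggr & is_dlbcl).sum())
    d = int((~is_aggr & ~is_dlbcl).sum())
    table = ContingencyTable2x2(a, b, c, d)
    oddsratio, p = fisher_exact_test(table)
    confusion = pd.crosstab(
        annotation.loc[matrix.columns, "entity"], pred, dropna=False
    )
    return ClassifierReport(
        predictions=pred,
        confusion=confusion,
        table=table,
        odds_ratio=oddsratio,
        p=p,
        seed=clf.seed,
        n_trees=clf.n_trees,
        params=clf.model.get_params(),
    )
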