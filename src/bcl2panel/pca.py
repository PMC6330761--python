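"""PCA factor maps with barycenter confidence ellipses.

Samples are projected onto principal components of the gene panel
(correlation PCA by default: genes centered and scaled to unit variance);
group means (barycenters) are summarized by the Hotelling confidence
ellipse of the mean, and variables are placed on the correlation circle by
their Pearson correlation with the first two score vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAModel:
    """Fitted principal components of a gene-by-sample matrix.

    Scores are per-sample coordinates, loadings per-gene weights; the
    centering/scaling vectors allow exact reconstruction of the input.
    """

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    explained_variance: np.ndarray
    explained_fraction: np.ndarray
    center: pd.Series
    scale: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        """Invert the transform: genes x samples matrix equal to the input."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T
        x = x * self.scale.to_numpy() + self.center.to_numpy()
        return pd.DataFrame(
            x.T, index=self.loadings.index, columns=self.scores.index
        )


@dataclass
class EllipseSpec:
    """Confidence region of a group barycenter in a 2-D score plane."""

    group: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the major axis
    level: float

    def contains(self, point) -> bool:
        """Whether a 2-D point falls inside the ellipse."""
        p = np.asarray(point, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        u = rot @ p
        a, b = self.semi_axes
        return float((u[0] / a) ** 2 + (u[1] / b) ** 2) <= 1.0


def pca_fit(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAModel:
    """Principal components of a gene-by-sample expression matrix.

    Samples are observations and genes variables. With ``scale=True``
    (default) this is correlation PCA; a zero-variance gene then raises an
    error naming the gene. Components are ordered by decreasing variance
    and signed so that each component's largest-magnitude loading is
    positive.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("PCA needs >=2 samples and >=2 genes")
    x = matrix.T.to_numpy(dtype=float)  # samples x genes
    n = x.shape[0]
    mu = x.mean(axis=0) if center else np.zeros(x.shape[1])
    xc = x - mu
    if scale:
        sd = xc.std(axis=0, ddof=1)
        dead = [g for g, s in zip(matrix.index, sd) if s == 0]
        if dead:
            raise ValueError(f"zero-variance gene(s) with scale=True: {dead[:5]}")
    else:
        sd = np.ones(x.shape[1])
    xs = xc / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    # fix the sign: make the largest-magnitude loading of each PC positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    variances = s**2 / max(n - 1, 1)
    total = variances.sum()
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return PCAModel(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comps),
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comps),
        explained_variance=variances,
        explained_fraction=variances / total if total > 0 else variances,
        center=pd.Series(mu, index=matrix.index),
        scale=pd.Series(sd, index=matrix.index),
    )


def confidence_ellipse(
    points: np.ndarray | pd.DataFrame, level: float = 0.95, group: str = ""
) -> EllipseSpec:
    """Hotelling confidence ellipse of a group's mean in a 2-D score plane.

    For n 2-D points with sample covariance S, the boundary satisfies
    ``(x - xbar)' S^-1 (x - xbar) = (2 (n-1) / (n (n-2))) F_{2, n-2}(level)``,
    an ellipse whose axes follow the eigen-structure of S. This is a
    confidence region of the barycenter, not of the data cloud; its
    semi-axes shrink like 1/sqrt(n).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an n x 2 array of scores")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("confidence ellipse needs >=3 points")
    if not (0 < level < 1):
        raise ValueError("confidence level must lie in (0, 1)")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals.min() <= 0 or not np.isfinite(eigvals).all():
        raise ValueError("singular covariance; cannot form an ellipse")
    c2 = (2.0 * (n - 1) / (n * (n - 2))) * stats.f.ppf(level, 2, n - 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    semi = np.sqrt(eigvals * c2)
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return EllipseSpec(
        group=group,
        center=(float(mean[0]), float(mean[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle=angle,
        level=level,
    )


def group_ellipses(
    model: PCAModel,
    annotation: pd.DataFrame,
    group_by: str = "entity",
    level: float = 0.95,
    components: tuple[str, str] = ("PC1", "PC2"),
) -> list[EllipseSpec]:
    """Barycenter ellipse per group on the first factor plane (groups with n < 3 skipped)."""
    scores = model.scores.loc[:, list(components)]
    labels = annotation.loc[scores.index, group_by]
    out = []
    for g in pd.unique(labels.dropna()):
        pts = scores[labels == g].to_numpy()
        if pts.shape[0] < 3:
            continue
        out.append(confidence_ellipse(pts, level=level, group=str(g)))
    return out


def variable_correlation_circle(model: PCAModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-variable coordinates on the correlation circle.

    Coordinate k of variable v is the Pearson correlation of v's values
    (across samples) with the k-th score vector; every variable lies within
    the unit disk of the first factor plane.
    """
    scores = model.scores.loc[matrix.columns]
    rows = {}
    for gene in matrix.index:
        v = matrix.loc[gene].to_numpy(dtype=float)
        if np.std(v) == 0:
            raise ValueError(f"zero-variance variable {gene!r}")
        rows[gene] = [
            float(stats.pearsonr(v, scores[c].to_numpy())[0])
            for c in ("PC1", "PC2")
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["r_PC1", "r_PC2"])
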