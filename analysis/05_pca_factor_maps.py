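#!/usr/bin/env python
"""PCA factor maps of the 12-gene panel with 95% barycenter ellipses.

Correlation PCA over all samples, per-entity barycenter confidence
ellipses on the PC1/PC2 plane, and the variable correlation circle —
the quantitative skeleton of the individual factor maps.
"""

import argparse
import dataclasses
from pathlib import Path

from bcl2panel import io, pca, synth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/corpus"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    genes = io.read_matrix(args.scratch / "genes.tsv")
    ann = io.read_annotation(args.scratch / "annotation_qc.tsv")
    panel = genes.loc[[g for g in synth.BCL2_FAMILY_GENES if g in genes.index]]

    model = pca.pca_fit(panel)
    ellipses = pca.group_ellipses(model, ann, group_by="entity", level=0.95)
    circle = pca.variable_correlation_circle(model, panel)

    args.results.mkdir(parents=True, exist_ok=True)
    io.write_json(
        {
            "explained_fraction": [round(float(f), 4) for f in model.explained_fraction],
            "ellipses": [dataclasses.asdict(e) for e in ellipses],
        },
        args.results / "05_pca_summary.json",
    )
    io.write_matrix(model.loadings.T, args.results / "05_pca_loadings.tsv")
    io.write_matrix(circle.T, args.results / "05_correlation_circle.tsv")
    io.write_matrix(model.scores.T, args.scratch / "pca_scores.tsv")

    pc12 = 100 * model.explained_fraction[:2].sum()
    print(
        f"PC1+PC2 explain {pc12:.1f}% of panel variance; "
        f"{len(ellipses)} entity barycenter ellipses written"
    )


if __name__ == "__main__":
    main()
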