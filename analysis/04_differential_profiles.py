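#!/usr/bin/env python
"""Nonparametric BCL2-family profiling: entity vs counterpart, tissue, subtype.

Wilcoxon-Mann-Whitney contrasts of each panel gene between every malignancy
and its normal counterpart (naive/memory B cells, centroblasts,
centrocytes, marginal-zone B cells, bone-marrow plasma cells), plus tissue
(PB/LN/BM/SPL) contrasts within MCL/FL/CLL/SMZL and molecular-subtype
contrasts, with the figure star convention and median-profile matrices.
"""

import argparse
from pathlib import Path

from bcl2panel import de, io, pipeline, synth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/corpus"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    genes = io.read_matrix(args.scratch / "genes.tsv")
    ann = io.read_annotation(args.scratch / "annotation_qc.tsv")
    panel = genes.loc[[g for g in synth.BCL2_FAMILY_GENES if g in genes.index]]

    cfg = synth.default_config()
    counterparts = pipeline.counterpart_contrasts(cfg)
    tissue_contrasts = [
        (f"{e}_LNvsPB", {"entity": e, "tissue": "LN"}, {"entity": e, "tissue": "PB"})
        for e in ("MCL", "FL", "CLL")
    ]
    subtype_contrasts = [
        ("MCL_SOX11negvspos", {"entity": "MCL", "subtype": "SOX11neg"},
         {"entity": "MCL", "subtype": "SOX11pos"}),
        ("DLBCL_ABCvsGCB", {"entity": "DLBCL", "subtype": "ABC"},
         {"entity": "DLBCL", "subtype": "GCB"}),
        ("MM_NFKBvsHY", {"entity": "MM", "subtype": "NFKB"},
         {"entity": "MM", "subtype": "HY"}),
    ]

    args.results.mkdir(parents=True, exist_ok=True)
    table = de.compare_profiles(panel, ann, counterparts + tissue_contrasts + subtype_contrasts)
    table.to_csv(args.results / "04_differential_profiles.tsv", sep="\t", index=False)

    medians = de.median_profile(panel, ann["entity"], zscore=True)
    io.write_matrix(medians, args.results / "04_median_profiles_zscored.tsv")

    sig = table[table["stars"] != "ns"] if "stars" in table else table
    print(
        f"{len(table)} gene-contrast tests, {len(sig)} significant; e.g. "
        + "; ".join(
            f"{r.contrast}/{r.gene} {r.stars}"
            for r in sig.head(3).itertuples()
        )
    )


if __name__ == "__main__":
    main()
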