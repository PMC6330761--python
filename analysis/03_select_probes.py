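#!/usr/bin/env python
"""Choose one probe per gene by RNA-seq concordance and collapse to genes.

Each probe is correlated (Pearson, across the 19 matched cell lines) with
its gene's RNA-seq row; the best probe is kept if r >= 0.5 with a
significant one-sided test. BAD and HRK drop out because their fidelity-0
probes track nothing; BBC3 is excluded a priori (suspected microRNA
cross-hybridization). Anchor QC then runs on the gene-level matrix.
"""

import argparse
from pathlib import Path

from bcl2panel import harmonize, io, probes, synth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/corpus"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-r", type=float, default=0.5)
    args = ap.parse_args()

    gep = io.read_matrix(args.scratch / "celllines_gep.tsv")
    rnaseq = io.read_matrix(args.scratch / "celllines_rnaseq.tsv")
    probe_map = io.read_probe_map(args.scratch / "probe_map.tsv")
    normalized = io.read_matrix(args.scratch / "normalized.tsv")
    ann = io.read_annotation(args.scratch / "annotation_qc.tsv")

    sel = probes.select_probes(
        gep, rnaseq, probe_map, min_r=args.min_r,
        exclude=synth.A_PRIORI_EXCLUDED_GENES,
    )
    gene_matrix = probes.collapse_to_genes(normalized, sel)
    io.write_matrix(gene_matrix, args.scratch / "genes.tsv")

    qc = harmonize.anchor_qc(gene_matrix, ann, list(synth.DEFAULT_ANCHOR_RULES))
    args.results.mkdir(parents=True, exist_ok=True)
    io.write_json(qc.to_dict(), args.results / "03_anchor_qc.json")

    frame = sel.to_frame()
    named = frame[
        frame["gene"].isin(
            synth.BCL2_FAMILY_GENES + synth.ZERO_FIDELITY_GENES
            + synth.A_PRIORI_EXCLUDED_GENES + synth.ANCHOR_GENES
        )
    ]
    named.to_csv(args.results / "03_panel_probe_selection.tsv", sep="\t", index=False)
    frame.to_csv(args.scratch / "probe_selection_full.tsv", sep="\t", index=False)
    print(
        f"selected {len(sel.selected)} genes, excluded {len(sel.excluded)}; "
        f"anchor QC pass={qc.all_passed}"
    )


if __name__ == "__main__":
    main()
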