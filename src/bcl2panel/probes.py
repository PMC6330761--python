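"""RNA-seq-guided probe selection and probe-to-gene collapse.

Microarray genes carry one to several probe sets of heterogeneous fidelity.
Using a panel of cell lines profiled on both platforms, each probe is
correlated with its gene's RNA-seq row; the best-correlated probe is kept,
and genes whose best probe fails the correlation criterion are excluded —
the fate of BAD and HRK, none of whose probes track RNA-seq. Genes can also
be excluded a priori (BBC3, whose probe set putatively cross-hybridizes
with MIR3191/MIR3190 transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REASON_LOW_CORRELATION = "low correlation with RNA-seq"
REASON_A_PRIORI = "a priori exclusion"
REASON_NO_RNASEQ = "gene absent from RNA-seq"


@dataclass
class ProbeSelection:
    """Outcome of probe selection: one chosen probe per retained gene.

    ``selected`` maps gene -> (probe id, correlation); ``excluded`` maps
    gene -> human-readable reason. A gene appears in exactly one of the two.
    """

    selected: dict[str, tuple[str, float]] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(self.selected)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "probe": p, "r": r, "status": "selected", "reason": ""}
            for g, (p, r) in sorted(self.selected.items())
        ] + [
            {"gene": g, "probe": "", "r": np.nan, "status": "excluded", "reason": why}
            for g, why in sorted(self.excluded.items())
        ]
        return pd.DataFrame(rows)


def select_probes(
    gep: pd.DataFrame,
    rnaseq: pd.DataFrame,
    probe_map: Mapping[str, str] | pd.Series,
    min_r: float = 0.5,
    alpha: float = 0.05,
    exclude: Sequence[str] = (),
    method: str = "pearson",
) -> ProbeSelection:
    """Choose one probe per gene by concordance with matched RNA-seq.

    Parameters
    ----------
    gep
        Probe-level expression over cell lines (rows = probes).
    rnaseq
        Gene-level expression over the same cell lines (rows = genes).
    probe_map
        probe id -> gene symbol, covering every row of `gep`.
    min_r, alpha
        A gene is retained only if its best probe reaches ``r >= min_r``
        with a significant one-sided (positive) correlation test.
    exclude
        Genes excluded a priori regardless of correlation.
    method
        ``"pearson"`` (default, on the log-scale values) or ``"spearman"``.

    Ties in the argmax correlation break by lexicographic probe id.
    """
    if isinstance(probe_map, pd.Series):
        probe_map = probe_map.to_dict()
    unmapped = [p for p in gep.index if p not in probe_map]
    if unmapped:
        raise KeyError(f"probes missing from map: {unmapped[:5]}")
    shared = gep.columns.intersection(rnaseq.columns)
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 shared cell lines between GEP and RNA-seq, found {len(shared)}"
        )
    if method == "pearson":
        corr = lambda x, y: stats.pearsonr(x, y, alternative="greater")
    elif method == "spearman":
        corr = lambda x, y: stats.spearmanr(x, y, alternative="greater")
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    by_gene: dict[str, list[str]] = {}
    for probe in gep.index:
        by_gene.setdefault(probe_map[probe], []).append(probe)

    sel = ProbeSelection()
    excluded_set = set(exclude)
    for gene in sorted(by_gene):
        if gene in excluded_set:
            sel.excluded[gene] = REASON_A_PRIORI
            continue
        if gene not in rnaseq.index:
            sel.excluded[gene] = REASON_NO_RNASEQ
            continue
        y = rnaseq.loc[gene, shared].to_numpy(dtype=float)
        best_probe, best_r, best_p = None, -np.inf, 1.0
        for probe in sorted(by_gene[gene]):
            x = gep.loc[probe, shared].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = corr(x, y)
            if r > best_r:
                best_probe, best_r, best_p = probe, float(r), float(p)
        if best_r < min_r or best_p >= alpha:
            sel.excluded[gene] = REASON_LOW_CORRELATION
        else:
            sel.selected[gene] = (best_probe, best_r)
    return sel


def collapse_to_genes(gep: pd.DataFrame, selection: ProbeSelection) -> pd.DataFrame:
    """Gene-level matrix copying each gene's chosen probe row verbatim.

    Excluded genes are absent from the output. Row order is sorted by gene
    symbol for determinism.
    """
    missing = [p for _, (p, _) in selection.selected.items() if p not in gep.index]
    if missing:
        raise KeyError(f"selected probes absent from matrix: {missing[:5]}")
    genes = sorted(selection.selected)
    rows = [gep.loc[selection.selected[g][0]] for g in genes]
    out = pd.DataFrame(rows, index=genes, columns=gep.columns)
    out.index.name = "gene"
    return out
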