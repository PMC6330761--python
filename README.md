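# bcl2panel

Expression profiling of the BCL2 gene family across mature B-cell
malignancies, and a search for transcriptional predictors of response to
the BCL2-selective BH3-mimetic venetoclax.

Mature B-cell neoplasms (MCL, BL, DLBCL, FL, BPLL, CLL, HCL, MALT, SMZL,
MM) depend to very different degrees on individual anti-apoptotic BCL2
proteins, and their overall response rates (ORR) to venetoclax monotherapy
range from ~79% (CLL) to ~18% (DLBCL). This package implements, as a
tested pipeline over synthetic data, the full analysis that connects pooled
multi-series microarray expression of the 12-gene BCL2 family panel
(*BCL2, BCL2L1, MCL1, BCL2L2, BCL2A1, BIK, PMAIP1, BMF, BID, BCL2L11, BAX,
BAK1*) to that clinical gradient. It is aimed at computational
hematology/transcriptomics researchers who want each stage as a reusable,
separately testable component.

## What the pipeline does

1. **Simulation** (`bcl2panel.synth`) — generates a pooled multi-series
   corpus (~1,200 patients, 10 entities plus normal B-cell counterparts,
   5,000 probes, batch offsets, tissue-of-origin effects, molecular
   subtypes, transformed FL/MALT drawn from a DLBCL-like profile) together
   with a matched 19-cell-line GEP/RNA-seq panel and a planted linear link
   between a chosen gene ratio and entity-level ORR. Every planted
   parameter is exposed as ground truth for recovery tests.
2. **Harmonization** (`bcl2panel.harmonize`) — quantile normalization of
   the pooled matrix, outlier removal by median pairwise Spearman
   correlation, and anchoring-gene QC (one-sided rank-sum checks that
   *CCND1*/*SOX11* are high in MCL, *CD38*/*SDC1* in MM, etc.).
3. **Probe selection** (`bcl2panel.probes`) — one probe per gene by Pearson
   concordance with matched RNA-seq across cell lines (argmax r, kept if
   r ≥ 0.5 with a significant one-sided test); *BAD* and *HRK* drop out
   because no probe tracks RNA-seq, and *BBC3* is excluded a priori for
   suspected *MIR3191/MIR3190* cross-hybridization.
4. **Differential profiling** (`bcl2panel.de`) — Wilcoxon–Mann–Whitney for
   two groups, Kruskal–Wallis for more, Fisher's exact test for counts, raw
   p-values with the star convention (\* <0.05 ... \*\*\*\* <0.0001),
   and group-median profile matrices.
5. **Factor maps** (`bcl2panel.pca`) — correlation PCA with per-group
   barycenter confidence ellipses (Hotelling region of the mean:
   boundary at (x−x̄)ᵀS⁻¹(x−x̄) = (2(n−1)/(n(n−2)))·F₂,ₙ₋₂(level)) and the
   variable correlation circle.
6. **Transformation classifier** (`bcl2panel.classify`) — a 1,000-tree
   random forest trained on the 12-gene panel predicts each FL/MALT
   sample's entity; re-labeling as DLBCL is cross-tabulated against
   aggressive (transformed) status and summarized by a Fisher odds ratio.
7. **Ratio biomarker** (`bcl2panel.ratio`) — all 49 candidate ratios
   (non-empty subsets of the efficacy pool {BCL2, BCL2L11, BAX} over
   non-empty subsets of the resistance pool {MCL1, BCL2L1, BCL2A1}),
   scored per sample as Σnumerator/Σdenominator on the log2 matrix and
   ranked by correlation with ORR. The headline statistic is

   **ratio = (BCL2 + BCL2L11 + BAX) / BCL2L1**,

   high where venetoclax works (CLL, MCL) and low where it does not
   (DLBCL, MM, BL).

## Worked example

```python
from bcl2panel import synth, pipeline, ratio

cfg = synth.demo_config(seed=7, samples_per_entity=25)
res = pipeline.run_full_pipeline(cfg, n_trees=500)

print(f"samples: {res.gene_matrix.shape[1]}, panel genes: {len(res.panel_genes)}")
print(f"anchor QC: {sum(r.passed for r in res.qc_report.rules)}/10 rules pass")
print(f"excluded genes: {sorted(res.selection.excluded)}")
t = res.classifier_report.table
print(f"FL/MALT transformation table [[{t.a},{t.b}],[{t.c},{t.d}]], "
      f"OR={res.classifier_report.odds_ratio:.3g}, p={res.classifier_report.p:.2g}")
ranking = ratio.rank_ratio_candidates(
    res.gene_matrix, res.annotation, res.ground_truth.implied_orr,
    summary="median-per-entity")
best = ranking.iloc[0]
print(f"best ratio: ({best['numerator']})/({best['denominator']}) "
      f"r={best['r']:.3f}, p={best['p']:.2g}")
```

prints

```
samples: 298, panel genes: 12
anchor QC: 10/10 rules pass
excluded genes: ['BAD', 'BBC3', 'HRK']
FL/MALT transformation table [[13,4],[0,33]], OR=inf, p=6.7e-09
best ratio: (BCL2+BCL2L11+BAX)/(BCL2L1) r=0.997, p=2.3e-10
```

Reading this: on a 298-sample demo corpus all ten anchoring-gene rules
pass, the three genes that cannot be measured reliably are excluded, 13 of
17 transformed FL/MALT samples are re-labeled DLBCL while no indolent
sample is (an infinite sample odds ratio — one zero cell), and the
exhaustive 49-candidate search returns the planted efficacy/resistance
ratio as the best ORR predictor.

## Analysis scripts

`analysis/01_simulate_corpus.py` … `analysis/07_ratio_biomarker.py` run the
same stages as numbered, narrative drivers at full scale (~1,200 samples,
5,000 probes), writing large intermediates under `scratch/` and summary
tables under `results/`. Run them in order; each prints what it found.

A thin `bcl2panel` CLI exposes the same stages for file-based use
(`bcl2panel simulate|harmonize|select-probes|de|pca|classify|ratio`).

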