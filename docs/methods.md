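# Methods

This note documents the models, parameter choices and numerical
conventions behind `bcl2panel`, and what the synthetic-data tests do and do
not establish about real pooled microarray corpora.

## The synthetic corpus

The generator emits post-summarization log2 intensities directly; raw CEL
processing and background correction are outside its scope. The latent
expression of gene *g* in sample *j* is

```
latent(g, j) = baseline(g) + entity_effect(g, e_j) + tissue_effect(g, t_j)
             + subtype_effect(g, s_j) + batch_offset(series_j) + N(0, noise_sd)
```

and each probe of *g* observes `fidelity·latent + (1−fidelity)·noise`,
where the noise channel is an independent N(baseline(g), probe_noise_sd)
draw. Key defaults, all in log2 units unless noted:

| parameter | default | rationale |
|---|---|---|
| baseline(g) | N(7, 1.5) truncated to [4, 12] | typical log2 array intensities; the floor prevents non-positive values that would break single-gene ratio denominators |
| noise_sd | 0.5 | within-entity biological + technical spread |
| batch_sd | 0.3 | per-series offset shared by all probes; enough structure to exercise pooled normalization and anchor QC without drowning biology |
| probe fidelity | first probe ~U(0.85, 0.95), extra probes ~U(0.3, 0.8) | heterogeneous probe quality; *BAD*/*HRK* get fidelity 0 (pure noise), *BBC3* ~U(0.1, 0.3) |
| entities | 10 malignancies (~1,185 patients in corpus proportions) + 6 normal populations (37 samples) | the pooled-compendium design |
| series_per_entity | 2 | minimal multi-series structure per entity |
| n_celllines | 19 | the size of the matched GEP/RNA-seq panel |
| orr_link_slope | 20 ORR percentage points per ratio unit | see below |

Entity effects plant the qualitative biology the analysis expects:
anti-apoptotic genes up and BH3-only genes (most prominently *BCL2L11*)
down in malignancies versus counterparts; a *BAX*-up/*BAK1*-down switch
except in MM and BL; *BCL2* highest in CLL/MCL/BPLL/HCL and low in BL/MM;
*BCL2L1* high in MM/DLBCL/BL. Each of the four planted ratio genes gets
its own heterogeneous across-entity profile so that no sub-ratio carries
the same information as the full (BCL2+BCL2L11+BAX)/BCL2L1 ratio. Tissue
effects encode niche biology: *BCL2L11* and *PMAIP1* repressed in LN/BM/SPL,
*BCL2L1* induced in LN. Subtype effects give *BIK* loss in SOX11− MCL, a
BCL2-high/BCL2L1-low profile to the t(11;14)/CCND1 myeloma subgroup, and
*BCL2L2/BCL2L11/BMF* induction in the NFKB subgroup. Anchor genes carry +3
in their signature entities. Transformed FL/MALT samples keep their
entity label with status "aggressive" but are drawn from the DLBCL effect
profile, mirroring histologic transformation.

The counterpart mapping (MCL/BPLL→naive B, BL/DLBCL→centroblast,
FL→centrocyte, CLL/HCL→memory B, MALT/SMZL→marginal-zone B, MM→bone-marrow
plasma cell) is a configuration table, not hard-coded, since
cell-of-origin assignments for some entities are debatable.

**The ORR link.** Entity-level overall response rate is
`clip(intercept + slope · median ratio(entity), 0, 100)`, computed on the
latent gene matrix; the intercept defaults to centering the mean ORR at
50%. The slope default (20) keeps implied ORRs inside the truncation range
for typical baseline draws — steeper links pile several entities onto the
0/100 bounds, creating ties that have no analog in the trial data. With
`orr_link_slope = 0` there is *no* planted relation; in that case entity
ORRs are drawn U(10, 90) independently of expression (seeded), because a
flat deterministic link would make every ORR identical and leave
correlations undefined.

**What the generator does not emulate:** probe sequence effects,
per-probe batch interactions, copy-number or mutational heterogeneity,
non-Gaussian heavy-tailed noise, and dependence between genes beyond the
shared entity/tissue/batch structure. Tests passing on this corpus show
the pipeline's estimators recover planted structure under the stated noise
model; they do not certify performance on real compendia, whose headline
statistics (e.g. a ratio–ORR correlation of a particular magnitude) depend
on the actual series pooled.

## Harmonization

Quantile normalization maps every sample onto the across-sample mean of
order statistics; ties within a sample receive the mean of the quantile
values their rank block spans. Normalization is applied once to the pooled
matrix, and no explicit batch regression is performed — cross-series
comparability is instead verified by anchoring-gene QC (one-sided
rank-sum, α = 0.05, pass requires p < α and positive median difference).
The outlier rule — median pairwise Spearman correlation below 0.5 — is a
scale-free criterion standard in array QC; the threshold is configurable
because no principled universal value exists.

## Probe selection

Pearson correlation on log-scale values is the default concordance measure
(Spearman behind a flag), with selection requiring both r ≥ 0.5 and a
one-sided p < 0.05 across the 19 shared cell lines. Ties in the argmax
break lexicographically by probe id for determinism. Note the exclusion of
fidelity-0 genes is itself statistical: with 19 points, a pure-noise probe
clears r = 0.5 with probability ≈ 1.5%, so a two-probe gene is excluded in
≈ 97% of datasets, not always.

## Statistics

* Rank-sum tests use the exact null when n₁+n₂ ≤ 20 without ties, else the
  normal approximation with tie and continuity corrections.
* Kruskal–Wallis is tie-corrected with a χ²(k−1) reference; an all-equal
  input returns H = 0, p = 1 rather than an error.
* Fisher's exact test reports the sample cross-product odds ratio
  (ad)/(bc), with the convention ∞ when bc = 0 < ad and undefined (NaN)
  when both products vanish; the two-sided p sums hypergeometric
  probabilities of all same-margin tables whose probability does not
  exceed the observed one (the probability-mass definition — stated
  explicitly because two-sided conventions differ).
* No multiple-testing correction is applied by default; raw p-values feed
  the star convention. Benjamini–Hochberg is available behind a flag.
* All group comparisons are unpaired.

## PCA and ellipses

Correlation PCA (center and scale) is the default; the scaling choice is
configurable since either convention is defensible for a 12-gene panel on
a common log2 scale. Component signs are fixed by making each component's
largest-magnitude loading positive. The group ellipse is a confidence
region of the *barycenter* (mean), not a data ellipse: with n points and
2-D sample covariance S, the boundary is
(x−x̄)ᵀS⁻¹(x−x̄) = (2(n−1)/(n(n−2)))·F₂,ₙ₋₂(level), so semi-axes shrink
like 1/√n. Groups with n < 3 or singular covariance are skipped or
rejected.

## Transformation classifier

Features are the 12 panel genes only — anchor genes are deliberately
excluded so the classifier sees nothing but BCL2-family biology. Training
uses all entities; the transformed FL/MALT samples under evaluation are
held out, while indolent FL/MALT remain in training by default (a flag
drops them too). Forest hyperparameters beyond the tree count (1,000 by
default) follow scikit-learn defaults and are recorded in the report. The
2×2 table is (status aggressive?) × (predicted DLBCL?); the report's OR
and p are reproducible from its own table via the Fisher routine.

## Ratio biomarker

Scores are computed directly on the normalized log2 values
(Σ numerator / Σ denominator); a linear-intensity option (2^x before
summing) exists because the scale of the original arithmetic is a genuine
ambiguity. Two correlation pairings are implemented. *Per-sample* (every
sample paired with its entity's ORR) is the inference default: an
entity-level Pearson on five points cannot produce the small p-values a
per-sample pairing can, making it the defensible reading for real-data
use. *Median-per-entity* is the mode used in recovery tests, because the
generator plants the link on entity medians; per-sample correlation
rewards candidates whose larger gene subsets average out within-entity
noise, which is a property of that estimator rather than of the planted
signal. Entities without trial ORR (BPLL, HCL, BL, SMZL, MALT) are scored
but excluded from correlations.

The null-link sanity check (planted candidate's rank uniform over the 49
candidates when no relation is planted) requires a fully exchangeable
null: besides setting the link slope to zero, all entity, tissue and
subtype effects on the six ratio genes are removed. With planted effects
left in place the candidate geometry is fixed across seeds and the rank of
any fixed candidate is provably non-uniform even though ORR is random.

## Problem sizes

Monte-Carlo tests use reduced corpora chosen to keep estimator behavior
representative: 35 genes/60 probes, 5 entities × 40 samples for ratio
recovery (100 seeds), 5 × 20 for the 490-seed null, 4 entities × 60 for
the transformation analysis (100 seeds, 200 trees), 100 seeds × 19 cell
lines for probe selection, and 1,000 replicates for type-I error and
ellipse coverage. The full-scale run (10 entities, ~1,220 samples, 5,000
probes, 1,000 trees) completes in well under a minute on one CPU.

## Known limitations

* The synthetic ORR link is exactly linear before truncation; real
  response rates aggregate heterogeneous trials.
* Quantile normalization assumes comparable global distributions; it
  cannot rescue a series whose biology differs wholesale, and the anchor
  QC would flag rather than fix such a failure.
* The probe-fidelity mixture is a one-parameter abstraction of
  hybridization quality; it reproduces selection behavior, not mechanism.
* Odds ratios from well-separated synthetic entities are frequently
  infinite (zero cells); reports preserve the raw cross-product and the
  acceptance script additionally reports a Haldane–Anscombe-corrected
  value for finiteness.
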