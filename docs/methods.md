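# Methods

## The measurement model

A pooled CRISPR-Cas9 knockout screen tracks the abundance of guide RNAs in a
cell population between an initial timepoint (T0) and the end of the
experiment. If knocking out gene *g* changes proliferation by a fitness
effect *f_g* (log2 depletion per population doubling, ≤ 0 for deleterious
loss), a guide's expected final count is `T0 · 2^(f · D)` after *D*
doublings. The per-gene CRISPR score (CS) is the z-scored log2 fold change:
lower CS means more deleterious loss-of-function. Everything in this package
is built around recovering and stratifying *f* from such counts.

## Scoring chain

1. **Multi-hit filter.** Guides whose sequence targets more than one locus
   can knock out both members of a young paralog pair, conflating single- and
   double-knockout fitness. Only guides with exactly one mapped target are
   scored; a report records removals per gene.
2. **Normalization.** Each sample column is scaled to a common read total
   (default 1e7).
3. **Fold change.** Replicates are averaged first, then
   `FC = log2((final + c) / (T0 + c))` with pseudocount `c = 5` per guide and
   cell line. Because the ratio is final/T0, depletion is already negative
   and no sign flip is applied; "lower CS = more deleterious" is enforced by
   a directed test rather than a convention copied from other tools.
4. **Gene summary.** Mean of a gene's guide fold changes (median behind a
   flag).
5. **z-score.** The pooled gene × cell-line values of a dataset are
   z-scored with population standard deviation (ddof = 0). The choice is
   immaterial at scale and fixed for reproducibility.
6. **Merging.** Datasets are restricted to shared genes and quantile
   normalized column-wise: every cell-line column is mapped onto the mean of
   sorted columns; tied entries receive the mean of the reference values
   their ranks span. This is the standard expression-array dialect; it makes
   every column's sorted vector identical (exactly) and the operation
   idempotent. Aggregated CS = mean over all cell lines of all datasets
   (mean and median aggregation correlate > 0.95 on the default synthetic
   study, so the cheaper mean is used).

## Labels

* **Singleton rule.** A gene is a singleton iff it has no non-self similarity
  hit with E-value < 0.001 over an aligned segment longer than 0.6 × the
  shorter protein (strict inequalities at both boundaries).
* **Pair registry.** Small-scale- and whole-genome-duplication pair lists are
  unioned, deduplicated irrespective of member order, origin recorded
  (`both` when shared). A gene in any pair is a paralog even if it passes the
  singleton rule (curated pair lists outrank the sequence screen; the
  conflict is logged). Remaining genes are `unclassified`.
* **Interaction modes.** Edges carrying co-fractionation, protein-RNA,
  co-localization, proximity label-MS or affinity capture-RNA codes are
  removed everywhere (they do not capture physical contact). The `direct`
  mode keeps only two-hybrid, biochemical activity, protein-peptide, PCA and
  Far Western. Matching is case- and punctuation-insensitive; unknown codes
  raise by default (lenient mode treats them as indirect and logs).
* **Homomer / heteromer.** A homomer is a gene with a self-edge; a pair is a
  heteromer iff an edge joins its members in the filtered network. Two
  sources are merged by intersection (positive only when both call positive).
* **Degree.** Distinct non-self partners. Self-edges are excluded from the
  count — degree measures partners, homomerization is a separate flag.
* **Essentiality.** Union of two reference sets per category; genes in both
  the essential and non-essential unions are conflicts, labelled `unknown`
  and logged.

## Statistics

* **Mann-Whitney U**, two-sided. For pooled n ≤ 12 the p-value is computed by
  full enumeration of all group assignments (ties handled naturally by
  mid-ranks); the two-sided p doubles the smaller tail probability, capped at
  1\. For larger samples, the normal approximation with tie correction and a
  0.5 continuity correction is used; the two agree within |Δp| ≤ 0.02 for
  groups of ≥ 6 without ties.
* **Fisher's exact test.** Sample odds ratio (ad)/(bc); zero margins give
  p = 1 with an undefined-OR flag, a zero cell an infinite/zero OR, flagged.
  Two-sided p by the probability-mass convention (sum of hypergeometric
  probabilities ≤ the observed table's), verified exactly against
  enumeration for every table with N ≤ 40.
* **Partial Spearman.** All variables rank-transformed (average ranks on
  ties; binary indicators are order-equivalent under ranking), partial
  correlation from the inverse correlation matrix of ranks, p from the
  t-distribution with n − 2 − k df. With no covariates this reduces exactly
  to ordinary Spearman. Perfectly correlated ranks short-circuit to ±1
  (the matrix inverse degenerates there).
* **Landscape.** Mean CS binned on a 20 × 20 grid over log2 expression ×
  log2(degree + 1) (the +1 offset handles zero-degree genes), spanning the
  1st–99th percentile window; cells with fewer than 5 genes are masked.
  Per-class densities use a Gaussian product kernel with Scott's-rule
  bandwidth, normalized to integrate to 1 over the window.
* **No multiple-testing correction** is applied anywhere; raw p-values are
  reported (a Benjamini-Hochberg column can be added by consumers, it never
  gates results here).

## Asymmetry analyses

P1 is the higher-expressed member of a pair in a context; ties break
lexicographically by gene id and are flagged. Two contexts are exposed:
per-cell-line orientation (used for pooled P1-vs-P2 comparisons and the
per-pair coupling correlations) and across-line mean orientation (for
pair-level aggregates). Asymmetry `A = |e1 − e2|/(e1 + e2)`; ΔCS =
CS(P1) − CS(P2). Binned summaries use equal-count bins with
mean ± 1.96 · SEM as the 95% CI. Per-pair Spearman correlations of A with ΔCS
require ≥ 4 cell lines; partial Pearson protein coregulation (protein of one
member vs the other, controlling both members' mRNA) requires ≥ 6 — both are
stability guards. Pair-level CS for the interface-size correlation is the
unweighted mean of the members' aggregated CS.

## Classifier comparison

The deleteriousness cutoff is `(min CS of non-essential + max CS of
essential)/2`; a gene is deleterious iff CS is strictly below it. Four
scikit-learn families with default hyperparameters (LinearSVC, random forest,
AdaBoost, decision tree) are evaluated over 5 repeated random 60/40 splits —
the protocol follows the "40% held out" reading; a strict 5-fold mode exists
behind a flag — with 2 bootstrap-balanced training sets per split. Balancing
resamples the larger class, with replacement, down to the smaller class's
size, on the training portion only (no test leakage). AUC is rank-based
(identical to trapezoidal ROC integration); importances are
impurity-based for trees and absolute coefficients on z-scored features for
the linear model, normalized to sum to 1.

## The synthetic study

The generator emulates the statistical structure of a multi-screen
meta-analysis, not any specific organism's data. Defaults (all in
`SimulationConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 2000 | catalog size (60% in 600 pairs, 25% singletons) |
| `n_cell_lines` | (3, 3, 1) | three screen datasets, seven cell lines total |
| `guides_per_gene` | 5 | library design |
| `library_size` | 500 | expected reads per guide per sample |
| `count_dispersion` | 0.15 | negative-binomial overdispersion (var = m + a·m²); 0 = noise-free limit |
| `doublings` | 8 | population doublings between T0 and final |
| `multi_hit_rate` | 0.2 | fraction of guides on pairs with dS < 1 hitting both members |
| `ds_scale`, `ds_max` | 1.5, 5 | dS ~ Exp(1.5) truncated at 5; pairs with larger dS are unreliable and excluded from dS-based analyses |
| `heteromer_fraction_of_pairs` | 0.15 | planted heteromers |
| `asymmetry_coupling` | 0.6 | per-line extra deleteriousness of P1 per unit asymmetry, heteromer pairs only |
| `protein_line_fraction` | 0.1 | protein matrix covers ~10% of cell lines, echoing typical protein/mRNA compendium proportions |

Fitness follows `f = −softplus(d)` with
`d = b_expr·z(expr) + b_degree·z(degree) + b_het·[heteromer gene] −
b_paralog·[paralog] + noise`, so every gene gets a strictly negative,
continuous effect and paralogs are buffered. Age groups are ordinal labels by
dS quantile (the simulator has no real phylogeny). Multi-hit guides combine
both targets' effects additively (a simple double-knockout model,
configurable). Counts are gamma-Poisson draws; `dispersion = 0` yields the
rounded expectation so degenerate configurations are exactly predictable.

Planted structure and how it is recoverable:

* heteromer genes get higher baseline expression and higher planted degree;
* heteromer pairs have smaller between-member baseline differences (lower
  asymmetry), a larger pair-shared expression fluctuation (higher
  coexpression), and a pair-shared protein residual on top of the
  mRNA-driven protein signal;
* the interaction network is an expected-degree random graph around the
  planted partner counts; edges joining members of *non*-heteromer pairs are
  removed and every heteromer pair/homomer gene gets a guaranteed edge with a
  kept method code in both sources, so heteromer flags are exactly
  recoverable in all-PPI mode (realized degree matches planted degree only up
  to the stochastic slack of the random graph);
* the similarity hit table is constructed to be exactly consistent with the
  class labels under the singleton rule;
* heteromer pairs are biased toward both-member homomers (the
  ancestral-homomer association);
* per cell line, the higher-expressed member of a heteromer pair receives an
  extra fitness penalty proportional to the pair's asymmetry in that line —
  the ΔCS–asymmetry coupling;
* gene sets are sampled from the pair pool at requested heteromer
  proportions spanning [0, 1]; when a pool runs short the set shrinks rather
  than dilutes, keeping extreme proportions exact;
* interface sizes (heteromer pairs only) increase with pair deleteriousness,
  planting the negative interface–CS correlation.

What the generator does **not** emulate: sequence-level guide effects
(efficiency, off-target spectra), copy-number artefacts, batch structure
between screens beyond independent libraries, real GO-style nested gene
sets, or the unexplained reversals real data show in a minority of age
groups. Passing tests therefore demonstrate that the pipeline recovers
effects *of the planted kind* at realistic sizes and noise — not that real
screens are free of the confounders the generator omits.

One caution the null analyses exposed: with `b_expr > 0` the expression →
fitness link alone induces an asymmetry–ΔCS relation (a more asymmetric pair
has a larger expression gap, hence a larger fitness gap). A clean "no
coupling" null therefore sets both `asymmetry_coupling = 0` and
`b_expr = 0`; the calibration tests and the acceptance script do exactly
that.

## Problem sizes in the test and acceptance runs

The default study (2,000 genes, 7 cell lines) runs the whole pipeline in a
few seconds, so the end-to-end and scoring-recovery checks use it directly.
Multi-seed rate estimates (multi-hit bias, class-effect detection, landscape
ordering, feature importance) use 800–1,200-gene studies with two datasets of
two lines — the package's chosen balance between statistical resolution and
turnaround. Asymmetry analyses need per-pair correlations across cell lines,
which the 3+3+1 default cannot support; they use a single-dataset
configuration with 10 cell lines (a scaled-down analogue of the large
many-line screen compendia such analyses target), 500 genes.

## Pipeline and reproducibility

All randomness flows from one root seed, expanded per stage through
`numpy.random.SeedSequence`, so stages are independently reproducible.
Each stage writes TSVs plus a `_complete.json` marker holding a hash of the
stage name, the config and all upstream hashes; re-runs skip stages whose
hash matches, and changing any upstream input invalidates everything
downstream. Identical (config, seed) runs are byte-identical, including
rendered PNGs (figures are pure views over the TSVs). Known limitation: the
cache keys on the config, not on external edits to stage outputs — editing a
TSV by hand without removing the marker will not trigger recomputation.
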