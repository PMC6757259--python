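# paralogcs

Gene duplication buffers cells against loss-of-function (LOF) mutations: when
one member of a paralog pair is knocked out, the other can often compensate.
But paralogous proteins that physically assemble with each other
(*heteromers of paralogs*) are functionally entangled — losing one member can
drag the other down with it, so the usual protection breaks down.
`paralogcs` is a meta-analysis pipeline for testing this hypothesis on
genome-wide CRISPR-Cas9 knockout screens, where the per-gene **CRISPR score
(CS)** — a z-scored log2 fold change of guide abundance over the course of
the screen — measures how deleterious a gene's LOF is for cell proliferation
(lower CS = more deleterious).

The package is aimed at computational biologists studying gene duplication,
dosage balance and protein-interaction networks. Because the real inputs
(screen read counts, interaction databases, expression compendia) are large,
versioned external resources, `paralogcs` ships a first-class **synthetic
study generator** that forward-simulates every input with planted effects,
so the entire analysis chain is testable against known ground truth.

## What it computes

* **Screen scoring** — guide-level read counts → per-gene, per-cell-line CS:
  multi-hit guides (targeting both members of a young, low-dS pair) are
  removed, samples are library-size normalised, replicates averaged,
  `FC = log2((final + c)/(T0 + c))` with pseudocount `c = 5`, guide FCs are
  averaged per gene and the pooled per-dataset values z-scored. Datasets are
  merged by quantile normalization over shared genes and mean aggregation.
* **Gene/pair labels** — singletons by the similarity rule (no non-self hit
  with E < 0.001 over > 0.6 × the shorter protein), paralog pairs as the
  non-redundant union of small-scale- and whole-genome-duplication lists,
  homomers (self-interaction) and heteromers (inter-member edge) from
  evidence-coded interaction edges in "all" and "direct" detection modes,
  two sources merged by intersection, essentiality as the union of reference
  sets.
* **Robustness statistics** — two-sided Mann-Whitney U (exact enumeration for
  pooled n ≤ 12), Fisher's exact test with sample odds ratio (ad)/(bc),
  partial Spearman correlations ρ(CS, heteromer status | expression, degree),
  expression-binned class comparisons, the 2-D **robustness landscape** of
  mean CS over (log2 expression × log2 interaction degree) with per-class
  kernel densities, and age-group stratification by dS.
* **Expression asymmetry** — per pair, P1 is the higher-expressed member and
  `A = (P1 − P2)/(P1 + P2)`; the analyses relate A to ΔCS = CS(P1) − CS(P2)
  within and across cell lines, quantify pair coexpression and
  post-transcriptional coregulation (partial Pearson of protein given mRNA),
  and correlate heteromer interface size with pair CS.
* **Classifier comparison** — genes labelled deleterious below the cutoff
  `(min CS of non-essentials + max CS of essentials)/2`; linear SVM, random
  forest, AdaBoost and decision tree trained on {heteromer status, log2
  expression, log2 degree} with bootstrap class balancing and repeated 60/40
  splits; rank-based ROC AUC and normalized feature importances.
* **Gene-set summaries** — per-set heteromer proportion vs mean paralog CS,
  Welch t-tests within sets, Spearman correlation across sets.

## Worked example

```python
import scipy.stats as st
from paralogcs import SimulationConfig, generate_study, score_study
from paralogcs.robustness import mann_whitney_u

cfg = SimulationConfig(seed=1)          # 2,000 genes, 600 pairs, 3 screens
study = generate_study(cfg)
scores = score_study(study)
agg = scores["aggregated"]              # per-gene CS, mean over 7 cell lines

truth = study.truth.genes["fitness"].reindex(agg.index)
print(f"recovery (Spearman): {st.spearmanr(agg, truth).statistic:.3f}")

klass = study.catalog["class"].reindex(agg.index)
res = mann_whitney_u(agg[klass == "paralog"], agg[klass == "singleton"])
print(f"paralog vs singleton CS: U={res.value:.0f}, p={res.p_value:.2e}")
print(f"median CS paralog    = {res.extra['median_a']:+.2f}")
print(f"median CS singleton  = {res.extra['median_b']:+.2f}")
```

prints

```
recovery (Spearman): 0.997
paralog vs singleton CS: U=455881, p=4.30e-64
median CS paralog    = +0.55
median CS singleton  = -0.41
```

The aggregated CS tracks the planted fitness effects almost perfectly, and
paralogs sit at visibly higher (less deleterious) scores than singletons —
the buffering signature the pipeline is built to measure.

The same analysis runs end to end from the shell:

```bash
paralogcs run --seed 1 --outdir results/run1     # simulate ... genesets
paralogcs report --outdir results/run1           # figures from the TSVs
```

Each stage writes tidy TSVs under `results/run1/<stage>/`; re-running with an
unchanged config hits the per-stage cache, and a fixed seed reproduces every
table byte for byte.

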