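# ovatools

Statistical toolkit for Drosophila gonad chromatin studies: tissue-
specificity classification, GC-aware count normalization, negative-binomial
differential expression with a consistency-across-ages contract, ectopic-
expression calling, gene-set over-representation, and ChIP-peak interval
analytics — plus a synthetic-data generator with planted ground truth so
the whole pipeline is testable without any sequencing data.

It is aimed at researchers analysing ovary (or cultured-cell knockdown)
RNA-seq together with ChIP-seq of a chromatin regulator, asking questions
like: *which tissue programme do the derepressed genes belong to, are
silent genes turning on ectopically, and where does the protein bind
relative to promoters and repetitive DNA?*

## The statistics at the core

**Tissue specificity.** For log2(RPKM) values x_1..x_n across n tissue
groups, τ = Σ_i (1 − x_i/max_j x_j) / (n − 1) ∈ [0, 1]; genes with τ ≥ 0.7
are tissue-specific and are assigned every tissue whose expression exceeds
mean + 1.5 SD. Genes with RPKM ≤ 2 everywhere are NotExpressed.

**Differential expression.** Counts ~ NB(μ, α) with variance μ + αμ²,
log-link GLM fit by IRLS with normalization offsets; method-of-moments
dispersion shrunk empirically Bayes toward a mean-trend; two-sided Wald
tests with BH correction; Cauchy-prior MAP shrinkage of log2 fold-changes.
In the 2×2 ovary design a gene is called only if the genotype effect is
significant in the additive model *and* the per-age fold-changes agree in
sign. Repeat IP-vs-mock enrichment anchors size factors on genomic bins
and requires agreement across antibodies.

**Ectopic expression.** A gene silent in wild type (mean RPKM < 2, rank
test p < 0.1) is ectopic in the mutant when its fold-change exceeds 2 and
a BH-corrected one-sided Mann-Whitney test gives q < 0.25.

**Interval analytics.** Peak merging, mock-peak subtraction, ±1 kb TSS
annotation, strand-oriented summit density profiles, %-coverage per 100-kb
bin, and segment-randomization overlap enrichment with empirical p-values.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from ovatools.simulate import SimulationConfig, generate_ovary_counts, generate_atlas
from ovatools.pipeline import run_ovary_analysis

cfg = SimulationConfig(seed=3, n_genes=1500)
counts, truth = generate_ovary_counts(cfg)
testis_like = {g: "testis" for g in truth.index[truth.is_testis_like]}
atlas, _ = generate_atlas(cfg, gene_ids=list(truth.index), specific_genes=testis_like)
cluster = counts.feature_meta.loc[truth.index[truth.in_cluster], ["start", "end"]]

bundle = run_ovary_analysis(counts, atlas, cluster, "out/", seed=3)
print(bundle["ectopic"].summary())
enr = bundle["enrichment"]
print(enr[enr.fdr < 0.05][["set", "direction", "k", "K", "n", "p", "mean_lfc"]])
```

prints

```
Ectopic-expression calls
  genes: 1500
  silent in WT: 150
  entered BH family (silent, fold > 2): 75
  ectopic (q < 0.25): 75
   set direction  k  K  n            p  mean_lfc
testis       top 14 15 86 3.285301e-17  3.859245
```

All 75 planted ectopic genes are recovered with no extra calls among the
75 planted silent nulls, and the planted testis-like gene set is the only
set over-represented in the top 1% of the shrunken-LFC ranking: 14 of the
15 top-ranked genes belong to it, with a mean log2 fold-change of 3.9 —
testis-programme genes are the most strongly derepressed. The cluster
summary in `bundle["cluster_summary"]` shows the planted 34-gene cluster's
mean LFC (1.71) far above the genome-wide mean (−0.001).

A command-line interface mirrors the library
(`ovatools synth|classify-tissues|normalize|de|ectopic|overrep|peaks|pipeline`);
try `ovatools --help`.

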