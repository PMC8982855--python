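# Methods

`ovatools` implements the statistical layer of a Drosophila ovary /
cultured-cell study of a chromatin protein: classifying genes by tissue
specificity, calling differential and ectopic expression from bulk RNA-seq
counts, and quantifying where ChIP peaks fall relative to genes and
repetitive DNA. This note records the models, the defaults and why they
were chosen, and what the synthetic data generator does and does not
emulate.

## Tissue-specificity (tau)

For a gene with log2(RPKM) values x_1..x_n over n tissue groups,

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1),

so tau = 0 for uniform expression and tau = 1 for single-tissue expression.
Conventions:

- Zero-RPKM cells are excluded from the log transform but enter tau as
  zero expression; log2 values below 0 (RPKM < 1) are clipped to 0 so the
  normalized profile stays in [0, 1].
- A gene with RPKM <= 2 (log2 <= 1) in **every** tissue is NotExpressed and
  gets no tau. The alternative reading (not expressed in at least one
  tissue) is available as `TauConfig(not_expressed_rule="any")`; the
  all-tissues rule is the default because it is the operational definition
  a summary table can be computed from.
- A gene with tau >= 0.70 is tissue-specific; its enriched tissues are
  those with log2(RPKM) above the across-tissue mean + 1.5 sample SDs (n-1
  denominator). Note the SD rule needs enough tissues to be able to fire:
  with 3 tissues the largest attainable z-score is 1.15, below 1.5. The
  study-scale panel (10-18 tissue groups) is well clear of this edge.

## Count normalization

The chain is filter -> within-lane GC full-quantile normalization ->
between-lane full-quantile normalization -> offsets:

1. Features with mean count <= 10 across all samples are dropped.
2. Within each sample, features are split into 10 equal-occupancy GC
   strata; each stratum's counts are replaced by the values at matching
   quantiles of that sample's pooled count distribution (linear
   interpolation between order statistics, tied counts share a value).
   This removes smooth GC-dependent bias while preserving within-stratum
   rank order, and is idempotent up to interpolation error.
3. Across samples, each sorted count vector is mapped onto the mean sorted
   vector (ties receive the mean of their positions' reference values),
   equalizing sequencing depth.
4. Offsets log((raw + 0.1)/(normalized + 0.1)) carry the normalization into
   the GLM so raw counts can be modelled directly. The 0.1 pseudocount
   bounds the offset away from log(0) for zero cells.

Between-lane normalization is unstratified by default (depth is a global
property); a GC-stratified variant is available via
`normalize_counts(..., stratified_between_lane=True)`.

## Negative-binomial GLM

Counts are modelled as NB with variance mu + alpha mu^2 and log link,
fitted per feature by batched IRLS (deviance tolerance 1e-8, max 100
iterations; non-converged and all-zero features are flagged, the latter
excluded from testing). Standard errors come from the Fisher information
at convergence; coefficients and SEs are reported in log2.

Dispersion: per-feature method-of-moments on design-group residuals
(alpha_raw = (s^2 - mean)/mean^2, with the denominator bias-corrected by
Var/n), shrunk toward a trend of binned arithmetic means over log mean.
The raw/trend mixing weight is set empirically Bayes: the between-feature
spread of raw estimates around the trend is moment-matched against their
sampling noise (sd(alpha_raw) ~ (alpha + 1/mean) sqrt(2/df)). Two choices
here matter for calibration at few replicates: the trend must be an
arithmetic (not log-space) mean, because raw MoM estimates are heavily
right-skewed and a geometric-mean-like fit underestimates alpha; and a
fixed mixing weight under-shrinks at ~4 residual df, inflating the Wald
type-I rate. With the adaptive weight the measured null p < 0.05 rate is
0.044-0.058 at alpha = 0.1 (3 vs 3, 2000 features) and conservative for
Poisson data. A constant count matrix yields alpha = 0 exactly.

Testing: two-sided normal Wald test of the chosen coefficient, BH step-up
over tested features (NaN features excluded from the family).

Shrinkage: the reported shrunken LFC is the MAP of a normal approximation
to the likelihood, N(lfc_mle, se^2), under a zero-centered Cauchy prior.
The prior scale defaults to moment matching on the panel
(scale^2 = mean(lfc^2) - mean(se^2), floored), so shrinkage adapts to the
real spread of effects. Shrinkage never changes sign, never increases
magnitude, and vanishes as SE -> 0. No attempt is made to reproduce any
particular external shrinkage estimator numerically.

### The two study designs

Ovary 2x2 (genotype x age): a gene is called differentially expressed iff
the genotype main effect of the additive model reaches FDR < 0.01 **and**
the per-age genotype fold-changes agree in sign (consistency contract). A
strict mode additionally removes genes with a significant genotype x age
interaction; it is off by default because ordinary ovary maturation changes
most genes and the sign-agreement rule already encodes the biological
requirement.

Repeat IP-vs-mock: library size factors are median-of-ratios computed on
genomic 1-kb bin features only, so genome-wide background reads anchor the
normalization and global IP/mock depth differences cannot masquerade as
enrichment. The condition coefficient is tested on repeat features (BH over
repeats only), and a repeat is reported enriched only when FDR < 0.05, the
IP coefficient is positive, and per-antibody contrasts agree in sign — a
binding call must not depend on which antibody was used.

RPKM is computed without the low-count filter (ectopic calling needs the
silent genes): count / size factor, divided by corrected library size in
millions and length in kb, with the corrected library being the per-sample
sum of size-factor-normalized counts.

## Ectopic expression

Two stages on RPKM matrices. (1) Silence in wild type: mean WT RPKM < 2.0
and a one-sided rank test supporting the replicates sitting below the
floor at p < 0.1. The published criterion names a rank test but not its
comparator; the default here is a Wilcoxon signed-rank of (RPKM - 2.0)
with the normal approximation, because the exact test's smallest one-sided
p at n = 3 is 0.125 and could never certify silence from triplicates. The
exact variant and a two-sample Mann-Whitney comparator are selectable in
`EctopicConfig`. (2) Among silent genes, those with
(mutant mean + 0.01)/(WT mean + 0.01) > 2 enter a one-sided Mann-Whitney U
test of mutant > WT, BH-corrected over exactly that entering set; q < 0.25
calls the gene ectopic. Genes failing the fold filter get q = NaN and stay
out of the BH family, which makes the calls invariant to adding expressed
genes to the input. The lenient q threshold matches the granularity of
rank tests at 2-3 replicates (minimum one-sided MW p at 3 vs 3 is 0.05, at
2 vs 2 it is 1/6).

## Over-representation and cluster summaries

Extremes are the ceil(pct * N) genes with highest/lowest shrunken LFC over
the universe of filter-surviving genes (boundary ties broken by gene id;
ranking by shrunken LFC, not p-value, mirrors fold-change-ranked displays).
Each gene set x direction gets an upper-tail hypergeometric p; one BH
family covers all tests in a run. Cluster summaries report mean LFC,
per-gene LFC, upregulated/ectopic counts, and inter-gene distances
computed as next body start minus previous body end, regardless of strand.

## Interval analytics

All coordinates are 0-based half-open; BED-family dialects are native, GTF
is converted on read. Conventions: book-ended intervals merge (scores
max-aggregate); mock subtraction removes whole peaks on any 1-bp overlap
(portion mode available); a gene is TSS-bound iff a peak intersects
[tss - w, tss + w + 1) with w = 1 kb; profile bins cover [-flank, flank)
strand-oriented (negative = upstream), anchored on summits by default
(midpoint fallback); bin coverage merges peaks first and normalizes the
final partial bin by its true width.

Overlap enrichment follows the segment-randomization design: each
simulation rewrites every query interval at an independent uniform position
(chromosome chosen proportional to valid start positions, lengths
preserved, excluded regions avoided by rejection, placed intervals may
overlap), and the empirical p is (1 + #sims >= observed)/(1 + n_sims), so
it is never zero. Isochore- or composition-matched randomization is out of
scope. For a single query of length L against a reference of length M on a
chromosome of length W the simulated expectation agrees with L*M/W.

## Synthetic data

The generator plants known structure at the study's scale so every stage
can be tested by parameter recovery. Defaults: 2000 genes, 2 genotypes x
2 ages x 3 replicates, 10 tissue groups, NB dispersion 0.05, planted
|LFC| = 2 for 10% of genes, 5% ectopic genes (WT RPKM 0.1-0.45, mutant
5-12, 2 x 10^7-read libraries) including a 34-gene adjacent testis-like
cluster, 5% silent-in-both genes with no true change (the ectopic null),
a disjoint 5% age effect, per-sample quadratic GC bias on log scale, and
ChIP peaks of which 60% sit with summits 150 bp upstream of a TSS
(sigma = 50 bp jitter) against a uniform background, with repeat counts
planted at 1.5-fold IP enrichment over unenriched genomic bins. Expression
programmes are rescaled so sum(RPKM x kb) = 1e6 holds on the small panel —
without this, measured RPKM on a 2000-gene panel is ~8x the planted
targets, an artifact of desk-scale simulation rather than of the method.

What the generator does **not** emulate: mappability and alignment
artifacts, isoform structure, GC bias at the fragment level (the bias is a
smooth per-sample gene-level curve), correlated replicate structure,
peak-caller score distributions, and reproducibility-score (IDR-style)
filtering — peak sets are consumed as already filtered. Passing recovery
tests therefore demonstrates correctness of the statistics and plumbing on
data satisfying the model's assumptions, not robustness to every artifact
of real sequencing data.

## Problem sizes

Tests and the acceptance script run the classifier at 5000 genes, the DE
calibration at 2000 features, the ovary/knockdown pipelines at 600-2000
genes with 3 replicates per group, and ChIP analyses with 4 x 400 peaks on
a 2 x 5-Mb genome with 10,000 randomization draws for the closed-form
overlap check — sizes chosen so the whole suite completes in well under a
minute on one core while keeping every estimator in its asymptotically
sensible regime.

## Known limitations

- The DE engine is deliberately simpler than full count-model packages: no
  Cook's-distance outlier handling, no independent filtering, no
  Cox-Reid-adjusted likelihood; numerical parity with them is a non-goal.
- Wald tests with plug-in dispersion are approximate at 2 replicates per
  group; calibration was verified at 3 per group.
- The inertness test ambiguity above means absolute ectopic counts depend
  on the configured comparator; the default is the only self-consistent
  reading at triplicate scale.
- Randomized placement treats chromosomes as uniform; no attempt is made
  to match local composition or chromatin context.
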