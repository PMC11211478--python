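# Methods

`dtcsig` implements the computational analyses used to characterize
drug-tolerant persister cells (DTCs) in oncogene-addicted lung cancer
models under targeted therapy: per-model differential expression, an
m-of-n cross-model consensus signature, permutation gene-set enrichment
with cross-model sharing, per-cell gene-set scoring and cluster profiling,
pseudo-bulk differential expression, and FUCCI cell-cycle fate analytics.
Every stage can be exercised offline against synthetic inputs with planted
ground truth.

## Differential expression (bulk_de)

Per gene, counts are modeled as negative binomial with mean `mu` and
variance `mu + alpha*mu^2`. Samples are normalized by median-of-ratios
size factors (the median, over genes positive in all samples, of the
count divided by the gene's geometric mean). The two-condition GLM with
log link is fitted on normalized counts by per-group Newton iterations,
vectorized across genes; `log2FC` is the condition coefficient in log2
units, tested with a Wald statistic against a normal reference and
BH-adjusted within each model. Genes with zero counts everywhere are
reported with NA p-values and excluded from BH; a group whose counts are
all zero falls back to a 0.5 pseudocount for the fold change.

**Dispersion.** The gene-level estimator is method-of-moments with a
Jensen-corrected denominator: over condition groups,
`alpha_g = sum_k (s2_gk − m_gk) / sum_k (m_gk^2 − s2_gk/n_k)` (the plain
`m^2` denominator overestimates `mu^2` by `Var(m)`, biasing `alpha` down).
With 2–3 replicates per group this estimator is far too noisy to plug into
a normal-reference Wald test — the statistic would behave like a t with
~4 df and inflate the null rejection rate several-fold — so gene-wise
values are shrunk toward a pooled estimate with weight
`df_gene/(df_gene + prior_df)`, `prior_df = 50` by default. The pool is
the *equal-weight* mean of the per-gene corrected ratios over genes whose
corrected denominator is at least a quarter of the uncorrected one:
equal weights keep the pooled estimator's effective sample size at the
number of genes, whereas a ratio-of-sums pool is dominated by the few
highest-expressed genes and wobbles enough from run to run to shift every
gene's Wald statistic together. All estimates are floored at `1e-8`.
Measured on all-null simulations (2000 genes, 3 vs 3, dispersion 0.1) the
null `p<0.05` rate is 0.051 ± 0.006 across seeds and the p-value
distribution passes a KS uniformity test at 5000 genes.

Known behavior: with a strongly unbalanced planted program (e.g. 10% of
the library up-regulated and nothing down), median-of-ratios normalization
leaves a genuine composition shift of order 0.1 log2 units in null genes.
This is a property of ratio-based normalization, not an implementation
artifact; the consensus thresholds sit well above it.

No Cook's-distance outlier handling, no independent filtering, no log2FC
shrinkage: the consensus rule thresholds the raw coefficient.

## Consensus signature (consensus_signature)

A gene enters the UP list when `p < alpha` and `log2FC > tau` in at least
`min_support` of the n models (DOWN symmetric with `log2FC < −tau`).
Defaults are the study constants `alpha = 0.01` (raw p; a
`use_adjusted_p` switch applies the cut to BH-adjusted values instead),
`tau = 0.5`, `min_support = 6` of 7. The candidate universe is the
intersection of the models' tested genes by default (`union` available);
genes missing from a model count as non-supporting there, a policy the
6-of-7 tolerance is designed to absorb. `mean_log2fc` averages over all
models, supporting or not; ranking is by mean log2FC descending with
lexicographic tie-breaks. Cohort overlap applies the same `(alpha, tau)`
criterion to an external DE table and reports `k/n (percent)` per
direction, counting signature genes absent from the cohort as
non-overlapping.

**Attainable recovery.** At the study's design (|log2FC| = 1.5,
dispersion 0.1, 3 vs 3), the standard error of a per-model log2FC
estimate is about 0.37, so the per-model probability of passing
`(p < 0.01, log2FC > 0.5)` is ≈ 0.92 for an affected gene — slightly
lower for down-regulated genes, whose treated-condition counts shrink
2^1.5-fold and inflate the Poisson part of the variance. A gene affected
in all 7 models is recovered (6-of-7) with probability ≈ 0.9; a gene
whose effect is absent in one model must pass in all 6 remaining models,
which caps its recovery near 0.92^6 ≈ 0.6. Recovery sensitivity under
per-gene dropout is therefore bounded well below 1 by the design itself;
precision stays at 1.0 because a 6-of-7 coincidence of null genes at
`p < 0.01` is vanishingly rare (the all-null expected signature size is
~1e-9 genes per 5000-gene run, and 10-seed runs return 0).

## Enrichment (enrichment)

Classic weighted Kolmogorov–Smirnov running sum on a ranked gene list
(default metric: signed log2FC; `signed_logp` available). Hits increment
by `|score|^p / N_R` (`p = 1`, `N_R` = total hit weight), misses decrement
by `1/(N − n_set)`; ES is the signed extremum. Null distribution by
gene-label permutation (random k-subsets of rank positions), matching
preranked practice — phenotype permutation is pointless at 3 samples per
condition. `NES = ES / mean(|null ES| of the same sign)` and the nominal p
is `(1 + #{same-sign null ≥ obs}) / (1 + #same-sign nulls)`, so it is
never exactly zero. Sharing counts per set the number of models with
`nominal p < 0.05` (flag) and `NES > 1` (up) or `NES < −1` (down), ordered
most-shared first. Permutations are O(k log k) per draw via hit-position
arithmetic; 500 sets × 1000 permutations on a 1000-gene ranking run in
about ten seconds. No multi-set FDR and no leading-edge extraction.

## Single-cell scoring and profiling (sc_scoring)

The per-cell score of gene set GS_x is the UMI fraction
`sum(UMI of GS_x in cell) / sum(UMI of cell)` — exactly additive over a
partition of the gene universe, invariant to rescaling a cell's counts,
and 1 for the all-genes set. Scores are emitted raw (no min–max rescale):
the [0,1] fraction scale is already comparable across datasets.
Cluster profiles normalize cells to counts-per-10k + log1p (the
conventional single-cell default; switchable off), average per
(gene, cluster), and z-score each gene across cluster means with the
population SD, mapping all-equal means to z = 0 rather than NaN so heat
map exports stay finite. Dot-plot tables add the fraction of cells with a
nonzero raw count. Phenotype association computes Pearson r between each
gene's per-cluster mean vector and a reference gene's (AGER for AT1,
SERPINE1 for mesenchymal, BPIFB1 for mucous/serous in the study's usage),
on cluster means rather than per-cell values, with the
simple-linear-regression two-sided p; genes with `r > 0.9` are flagged.
At least 3 clusters are required for a p-value; a zero-variance reference
is an error.

## Pseudo-bulk (pseudobulk)

Cells of each condition are shuffled with a seeded generator and dealt
round-robin into k = 3 groups, so group sizes differ by at most one and
gene-wise totals are conserved exactly; pseudo-sample counts are column
sums. Randomization is unstratified within condition. Downstream testing
reuses this package's NB Wald test — one DE engine for the whole
artifact — rather than replicating an edgeR-style quasi-likelihood fit;
with hundreds of cells per condition the planted 10-fold markers are
recovered at `p_adj < 0.05` with sensitivity above 0.8, and the
split-one-population null stays uniform.

## FUCCI analytics (fucci)

Tracks are two-channel (red = G1 reporter, green = S/G2/M reporter)
hourly intensity series with division and death flags. Phase calling is
a per-channel hysteresis state machine: a channel switches on above
`threshold × (1 + f)` and off below `threshold × (1 − f)` (`f = 0.2`,
thresholds 300/300 on a 0–1000 intensity scale), suppressing flicker;
red-only = G1, green-only = S/G2, both = transition, neither = previous
call carried forward, and the dead flag overrides everything. Population
curves count alive cells per phase per timepoint, normalized to the
baseline total by default (per-timepoint normalization available);
"transition" cells count toward the total but neither G1 nor S/G2.
Fate classification, per cell entering S/G2: division after entry =
mitosis; death before any division = death; return to G1 with neither =
endoreplication / mitotic slippage; still in S/G2 at track end = censored
(reported, excluded from percentages). Summaries give per-condition fate
percentages over uncensored cells (summing to 100) and mean ± SEM phase
durations. Early escapers are cells with a G1→S/G2 transition at or
after a configurable 24 h of treatment — the study describes escapers
qualitatively, so the cutoff is exposed rather than asserted.

## Synthetic data (synthetic_data)

The generators define the conditions under which everything above is
tested; they emulate study designs, not full biological realism — no
batch effects, ambient RNA, doublets or gene-length bias, so passing
tests demonstrate algorithmic correctness and statistical calibration,
not robustness to those artifacts.

* **Bulk models** — 7 models by default, 3 vs 3 samples, gamma-Poisson
  (NB) counts with dispersion 0.1 (typical bulk RNA-seq overdispersion),
  shared log-normal gene baselines (sd 1.0 in log) with per-model jitter
  (sd 0.2), mean depth 2,000,000 counts over 5000 genes (≈400 per gene,
  the per-gene depth of a ~20M-read library over a 20k-gene
  transcriptome, desk-scaled), per-sample library jitter CV 0.1. The
  planted program (defaults 212 up / 495 down at |log2FC| = 1.5 — the
  consensus signature's size) multiplies treated means by 2^±effect
  exactly; each planted gene is silent in `dropout_models_per_gene`
  (default 1) uniformly chosen models, the mechanism behind a 6-of-7
  support band. The small library shift the program causes is left to
  size-factor normalization.
* **Single cell** — per-cell totals Poisson around 5000 UMIs, multinomial
  gene draws from a shared log-normal baseline with each cluster's marker
  mass multiplied by its fold (default 8). The default cluster layout
  mirrors the persister landscape: untreated cycling cells plus AT1-like
  (AGER, PDPN, HOPX, CAV1, CLIC5), mesenchymal (SERPINE1, VIM, CDH2, FN1,
  TAGLN) and mucous/serous (BPIFB1, MUC5B, SCGB1A1, LTF, LYZ) clusters.
* **Tracks** — 20 cells per condition by default (the study's fate-
  tracking cohort size), exponential G1 (mean 8 h) and S/G2 (mean 14 h)
  durations, planted fates drawn from `fate_probs`, channels on a 0–1000
  scale (low 30, high 800) with logistic transitions (τ = 1 h) and
  Gaussian noise (sd 20 default). Mitosis ends the track at the division
  row (offspring untracked); endoreplication returns the channels to a
  G1 pattern; death zeroes both channels with the dead flag absorbing.
  Truth phases come from thresholding the *noiseless* trajectories at
  the channel midpoint, so noisy-call agreement isolates noise
  robustness; exponential durations give a closed-form hypoexponential
  survival curve for checking population dynamics.

All generators are byte-deterministic given their seed.

## Numerical conventions

Ties in every ranking break lexicographically by gene symbol. Gene
identity is uppercase symbol, exact match, duplicates collapsed by
summation (preserving the totals the UMI-fraction score divides by); no
alias resolution. BH adjustment is the step-up transform, monotone and
capped at 1. Newton iterations for the NB group mean start at the
alpha = 0 solution `sum(y)/n`, halve on negative steps and stop at
relative tolerance 1e-10 or 50 iterations.

## Problem sizes used in the checks

Acceptance-style checks run at: 7 models × 5000 genes × 6 samples for
consensus recovery and 10-seed null safety; 2000 genes for DE
calibration; 500 random sets × 1000 permutations on a 1000-gene ranking
for enrichment calibration; 300–400 cells for scoring, pseudo-bulk and
fate-recovery checks. A full run of the acceptance script takes well
under a minute on one CPU.

## Known limitations

* The Wald test with moderated moments dispersion approximates, but is
  not, DESeq2: no dispersion trend over the mean, no MAP shrinkage, no
  outlier refitting. On real heterogeneous-dispersion data the constant
  `prior_df` moderation is cruder than an empirical-Bayes trend.
* Consensus recovery under per-gene dropout is power-limited by design
  (see above); the signature's precision, not its sensitivity, is the
  robust quantity at 3 vs 3 replication.
* Gene-label permutation GSEA ignores inter-gene correlation, as
  preranked GSEA does; nominal p-values are exact only under the
  exchangeable-null reading.
* Phase calling assumes two anti-correlated reporters on a common
  intensity scale; it does not segment images or reconstruct lineages
  across divisions.
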