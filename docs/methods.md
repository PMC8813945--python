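# Methods

This note documents the statistical model behind `regmeth`, the synthetic
cohort it is validated on, and the design choices made where the analysis
was genuinely open.

## Region-level differential methylation

The unit of analysis is the annotated region (promoter or enhancer), not
the CpG. A region's methylation in a sample is the unweighted arithmetic
mean of its non-missing CpG beta values; site-count weighting was
considered and rejected — it complicates the estimand without a principled
weighting rule, and region sizes here are small (4–12 covered CpGs).
Regions where any sample has zero covered CpGs are dropped as untestable
and excluded from multiplicity correction.

Testing happens on M-values, M = log₂(β/(1−β)) with β clipped to
[10⁻³, 1−10⁻³]: the logit transform stabilises the variance of beta values
near the boundaries, where the beta scale compresses. Because the cohort is
paired, each region is tested with a one-sample t-test on the per-patient
differences of M-values of region means (tumor − normal), using
pairwise-complete patients per region. A region whose differences are all
zero gets p = 1 by convention. Benjamini–Hochberg runs separately within
promoters and within enhancers — the two annotation universes are analysed
and reported as separate families throughout — and a region is a DMR at
q < 0.01. The reported effect size `delta_beta` stays on the beta scale
(mean paired difference), since that is the scale practitioners read.

This paired-t-on-region-means procedure is a deliberate, documented choice
of test: it is transparent, exactly reproducible, and preserves the
decision structure (region-level p, BH within kind, FDR < 0.01) without
depending on any array-processing framework's internal region statistic.
It is not claimed to be numerically equivalent to such internal statistics.

## Differential expression

Counts are normalized with median-of-ratios size factors (geometric-mean
reference over genes with all-nonzero counts; upper-quartile fallback,
rescaled to geometric mean 1, when no such gene exists). Genes are tested
with a paired t-test on per-patient differences of log₂(normalized + 1);
pseudocount 1 keeps zeros finite. log₂FC is the mean paired difference. A
gene is a DEG iff |log₂FC| > 2 — strictly, so a gene at exactly 4-fold does
not qualify — and BH q < 0.01. A negative-binomial model with dispersion
shrinkage would be more powerful at small n; at 37 pairs and the planted
3-unit log-fold changes the paired t is ample, and it keeps the test
self-contained and exactly checkable. A gene whose paired differences have
zero variance gets p = 1 by convention.

## Target maps and functional DMRs

Promoter targets are the downstream gene, one-to-one; a promoter referenced
by two genes is a data error and raises. Enhancer targets come from the
enhancer–promoter interaction table after discarding links with PET support
below 5 (duplicate links collapse to their maximum support); links are
many-to-many. Both maps pass through a coding-gene whitelist. A (DMR,
target) pair is *functional* when the target is a DEG changing opposite to
the methylation (hypo ∧ up, hyper ∧ down); a DMR is functional when at
least one of its pairs is. seDMRs are super-enhancer intervals overlapping
at least one called eDMR (any overlap); their target set is the union over
overlapping eDMRs and the functional filter is re-applied to those targets.

## Embedding and cluster entropy

Sample profiles over a DMR subset are embedded with t-SNE at perplexity 10
(with a guard rejecting perplexity ≥ (n−1)/3) or with UMAP on the first 10
principal components; both are seeded. k-means with k = 2 and 10 restarts
runs on the 2-D embedding coordinates — running it on raw beta profiles is
available by flag; the embedding route was chosen as the default because
the entropy score is meant to grade the *visualised* separation. Separation
is scored by the size-weighted Shannon entropy of tissue labels within
clusters, in bits; with two tissue labels it lies in [0, 1], 0 meaning the
clusters reproduce the tumor/normal split exactly. Entropy is invariant to
cluster relabelling and tissue-label swap, and can only decrease when a
cluster is split (concavity of entropy) — both properties are tested.

## Specificity and correlation

Tumor-type-specific genes are genes over-expressed in the focal panel group
against **every** comparison group (conjunction), at fold change > 2 of
group means and one-sided rank-test p < 0.05. The groups are unpaired, so
the one-sided Mann–Whitney rank-sum test is used — a signed-rank test has
no pairing to act on here. Methylation–expression correlation is Spearman's
ρ per (DMR, target) link across tumor and normal cohort samples jointly
(tumor-only is available by restricting the sample list); using both
tissues maximises the dynamic range that the inverse coupling acts over.
Genes whose maximum normalized expression is below 1 are excluded — the
filter is max-based (a gene must be < 1 in *all* samples to be dropped);
the any-sample reading would silently remove most of the transcriptome.
Degenerate (constant) series have undefined ρ and are dropped with a
count. The specific-vs-other contrast is a two-sided Mann–Whitney test on
the two ρ samples.

## Enrichment statistics

Gene-set enrichment is the one-sided ("greater") Fisher exact test on the
2×2 table of query × set membership within the gene universe, sets
intersected with the universe first, BH across the collection. Odds ratios
are reported raw (ad/bc, with ∞ when bc = 0 and ad > 0) plus a
Haldane-corrected column (+0.5 per cell) for plotting.

SNP proximity: a SNP counts as profiled when it lies within the window
(default 5 kb, measured symmetrically from region edges; window 0 reduces
to containment) of at least one tested region, and as a hit when within the
window of a DMR. The p-value is the exact upper binomial tail P(X ≥ k)
with null hit probability p₀ = (number of DMRs)/(number of tested regions):
under exchangeability, a profiled SNP's region is a DMR with exactly that
probability. Genome-length-weighted backgrounds were rejected as
unidentifiable from region tables alone; a user-supplied p₀ is accepted.
Edge-based distance was chosen over midpoint-based; for the region sizes
here (≤ 2 kb) the two differ by at most ~1 kb of window.

## Immune infiltration

Infiltration fractions (cell type × sample, columns summing to 1) are an
input: deconvolution is a separate, upstream problem. Differential
abundance uses the paired Wilcoxon signed-rank test with BH across cell
types (q < 0.01). IMRs are (region, cell type) pairs with Spearman q < 0.01,
BH applied jointly across all pairs within a region kind (per-cell-type
correction available by flag); a *region* is an IMR when any of its pairs
qualifies — the per-region reading is what the DMR-overlap proportions are
defined on. Correlations run on tumor samples only by default
(infiltration is a property of the tumor microenvironment; an all-samples
mode exists). The IMR × DMR 2×2 is tallied over the kind's testable
regions; PMD stratification is any-overlap with a PMD interval and is an
exhaustive, disjoint partition.

## The synthetic cohort

The generator emulates the full study: paired tumor/normal samples, a
region-annotated genome, and every downstream table, with planted truth
for scoring. What it models, and what it does not:

- **Betas** are logit-normal: site value = inverse-logit of (region mean +
  per-site offset [s.d. 0.3] + patient effect [s.d. 0.4, shared between a
  patient's tumor and normal sample, making paired tests strictly more
  powerful than unpaired — the point of the paired design] + noise
  [s.d. 0.8]). Region base means are uniform on (0.08, 0.92). A planted
  DMR shifts the tumor-side region mean by ±`delta_beta` **on the beta
  scale**: the logit offset is solved numerically (64-node Gauss–Hermite
  expectation of the inverse-logit, then root finding) so the expected
  shift is exact — verified by a Monte-Carlo contract test at ±0.02. A
  Beta-distributed noise model was rejected: logit-normal parameterises
  patient effects and region shifts additively on one scale.
- **Defaults are the study conditions**: 37 pairs; planted DMR fractions
  per kind 0.22/0.095 (promoter hypo/hyper) and 0.17/0.075 (enhancer),
  matching the observed pDMR/eDMR rates and their hypomethylation
  dominance; `delta_beta` = 0.25 and the dispersions above are realistic
  array-scale choices (the real cohort's effect-size distribution is not
  published as parameters). Tests use smaller cohorts for speed; the
  scenario sizes are stated in the tests themselves.
- **Counts** are negative-binomial (dispersion 0.1) with lognormal gene
  baselines, per-sample library factors, and a per-gene patient effect. A
  `coupling_fraction` (0.3) of planted DMRs get a coupled target gene with
  log₂FC = 3 opposite in sign to the methylation shift — promoter DMRs
  couple to their downstream gene, enhancer DMRs to a dedicated gene linked
  through the EPI map with PET ≥ 6. Coupled genes receive no other EPI
  links, so the planted (region, gene) truth table is unambiguous.
- **Pan-cancer panel**: unpaired lognormal groups sharing gene baselines;
  planted specific genes (drawn from the hypo-coupled genes) are boosted
  8-fold in the focal group only. Groups are unpaired because the
  specificity analysis compares unpaired groups.
- **Infiltration**: fractions are a softmax of Gaussian latents; three cell
  types get tumor-side latent shifts (differential abundance). 120 planted
  (region, cell type) couplings add ±1.2 × the cell type's latent to the
  region's logit methylation in tumor samples, drawn 70% from enhancer
  DMRs, 12% promoter DMRs, 12% non-DMR enhancers, 6% non-DMR promoters —
  the enhancer-dominant structure the IMR analysis is meant to detect, at
  planted counts large enough that the odds-ratio ordering is a multi-sigma
  effect rather than a coin flip.
- **SNPs** are placed within 4.5 kb of a region chosen either from the
  planted DMRs (probability `snp_near_dmr_prob`) or uniformly from all
  tested regions. Regions are laid out ≥ 12 kb apart, more than twice the
  5 kb window, so each SNP is within the window of exactly the region it
  was placed at — this makes the binomial null exact by construction.
- **Not modelled**: array chemistry (two probe designs, detection
  p-values), probe cross-reactivity, read-level RNA-seq, copy-number or
  purity effects, and any spatial autocorrelation of methylation beyond
  region membership. Passing tests therefore demonstrate the *inference
  machinery* (error control, recovery, orderings) under the planted model,
  not robustness to those real-data artefacts.

## Numerical and reproducibility choices

- One seeded `numpy` generator drives the whole bundle; identical config +
  seed gives byte-identical outputs, and the pipeline's `manifest.json`
  (config echo, per-stage counts, file checksums, seed registry) is itself
  byte-reproducible — wall-clock timings are logged, not written into it,
  precisely so manifests can be compared.
- BH is delegated to `statsmodels`, Fisher/binomial/rank tests to `scipy`,
  t-SNE/k-means/PCA to `scikit-learn`, UMAP to `umap-learn`; the in-package
  Spearman is rank-then-Pearson vectorised over region × cell-type
  matrices, cross-checked against `scipy.stats.spearmanr` to 10⁻¹². Tests
  verify each kernel against independent hand-rolled oracles (hypergeometric
  tail enumeration, explicit binomial sums, a reference step-up).
- Ties: Spearman uses average ranks; k-means label permutation is treated
  as irrelevant everywhere downstream; entropy handles empty cells by the
  0·log 0 = 0 convention.
- Degenerate inputs fail loudly (empty universes, too few pairs/samples,
  start ≥ end rows with the offending line number) or are dropped with a
  logged count (constant correlation series, untestable regions) — never
  silently imputed.

## Known limitations

- The region test assumes approximate normality of paired M-value
  differences; with very few covered CpGs and extreme betas the t reference
  is only approximate (BH at q < 0.01 leaves headroom, and the null
  simulations bound the realised false-call rate).
- The binomial SNP test conditions on the DMR calls; DMR-calling
  uncertainty is not propagated into p₀.
- Entropy saturates at 0 well before separation differences vanish, so at
  strong planted signal the pDMR/eDMR comparison is only an ordering
  (≤), not a margin.
- The specificity contrast pools each kind's links; it does not model
  correlation between links sharing a region or a gene.
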