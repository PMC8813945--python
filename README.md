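# regmeth

Promoter- versus enhancer-level DNA methylation analysis for paired
tumor/normal cohorts.

Bulk methylation arrays now cover hundreds of thousands of CpG sites in
*enhancer* regions, not just promoters. For a cohort of patients with
matched tumor and adjacent-normal tissue, this package asks where the
regulatory action is: are the methylation changes that separate tumors from
normal tissue, drive target-gene expression, and track immune infiltration
sitting on promoters or on enhancers? It was built for epigenomics analysts
who have a clean beta-value matrix (array preprocessing done), region
annotations, an enhancer–promoter interaction map, matched expression
counts, and deconvolved immune-infiltration fractions — and who want the
whole promoter-vs-enhancer comparison as one reproducible, tested pipeline.

## The analysis

Let β<sub>ij</sub> ∈ (0,1) be the methylation fraction of CpG *i* in sample
*j*, and let a *region* (promoter or enhancer) summarise its CpGs by the
mean beta. The pipeline:

1. **DMR calling.** Per region, a paired t-test on per-patient differences
   of M-values, M = log₂(β/(1−β)), of region-mean betas; Benjamini–Hochberg
   within each region kind; a region is a DMR when q < 0.01, *hypo*methylated
   when the tumor mean is lower.
2. **Target mapping.** Promoter → downstream gene (one-to-one); enhancer →
   genes from a chromatin-interaction (EPI) map filtered to PET counts ≥ 5;
   targets restricted to a coding-gene whitelist.
3. **Differential expression.** Median-of-ratios normalization, paired t on
   log₂(normalized+1); DEG iff |log₂FC| > 2 (strict) and q < 0.01.
4. **Functional DMRs.** A DMR is functional when a target gene is a DEG in
   the *opposite* direction (hypo ∧ up, or hyper ∧ down). Super-enhancer
   DMRs (seDMRs) are super-enhancers overlapping called eDMRs.
5. **Cluster entropy.** tSNE (perplexity 10) and UMAP (on 10 PCs) of sample
   profiles over pDMRs alone, eDMRs alone, or all DMRs; k-means (k = 2);
   separation scored by H = Σ_c (n_c/N)·[−Σ_t p_ct log₂ p_ct] over tissue
   labels t within clusters (0 = perfect tumor/normal split).
6. **Specificity correlation.** Tumor-type-specific genes (fold change > 2
   and one-sided rank-test p < 0.05 against *every* comparison group of a
   pan-cancer panel) are contrasted against other target genes in their
   Spearman ρ between region methylation and expression.
7. **Enrichment.** Gene sets: one-sided Fisher exact tests with BH. Risk
   SNPs: each profiled SNP either lies within 5 kb of a DMR or not; the
   upper binomial tail P(X ≥ k) with null hit probability p₀ = (DMRs among
   tested regions) tests proximity enrichment.
8. **Immune infiltration.** Differentially abundant cell types (paired
   signed-rank, q < 0.01); infiltration-associated methylation regions
   (IMRs) by Spearman correlation of region beta with cell-type fractions
   (BH jointly per kind, q < 0.01); IMR × DMR 2×2 odds ratios and
   stratification by partially methylated domains (PMDs).

A synthetic cohort generator (`regmeth.cohort`) emulates every input with
planted ground truth — paired logit-normal betas with planted DMRs,
negative-binomial counts with planted inverse coupling, a pan-cancer panel
with planted specific genes, infiltration fractions coupled to chosen
regions, SNPs placed near/far from DMRs — so the full pipeline is testable
without any external download.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic cohort (37 tumor/normal pairs, 2000 promoters, 3000
enhancers, ~50k CpGs):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_call_dmrs.py
```

```
planted promoter DMRs: 630 (440 hypo / 190 hyper)
planted enhancer DMRs: 735 (510 hypo / 225 hyper)
...
promoter: 632 DMRs of 2000 tested (440 hypo / 192 hyper)
enhancer: 738 DMRs of 3000 tested (513 hypo / 225 hyper)
recovery vs planted truth: sensitivity 1.000, observed FDR 0.004, direction accuracy 1.000
```

The caller recovers essentially every planted DMR at the planted
hypo/hyper ratio (hypomethylation dominant) with the false-discovery rate
held far below the nominal 1%. Continuing:

```bash
python analysis/06_specificity_correlation.py
python analysis/08_immune_infiltration.py
```

```
    kind            p  median_rho_specific  median_rho_other
promoter 3.845453e-07            -0.703813         -0.045139
enhancer 3.590700e-10            -0.713528         -0.025976
...
    kind  prop_dmr  prop_nondmr  odds_ratio
promoter  0.022152     0.005117    4.404531
enhancer  0.113821     0.006189   20.623853
```

Planted tumor-type-specific genes show a median methylation–expression
ρ ≈ −0.7 against ≈ 0 for other genes, and the planted infiltration
coupling — concentrated on enhancer DMRs — is recovered as a much larger
IMR/DMR odds ratio for enhancers than promoters, the package's analogue of
the enhancer-dominance result it is designed to detect.

The same pipeline is scriptable in one call:

```bash
regmeth run --seed 1 --outdir results/run      # full pipeline, synthetic mode
regmeth simulate --outdir results/cohort       # just the cohort tables
regmeth report results/run                     # entropy / enrichment summary
```

or on your own data by pointing a YAML config's `input_dir` at a directory
laid out like `regmeth simulate`'s output.

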