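# Methods

This note documents the models, numerical choices and limitations behind
`gg1tx`, in the order the pipeline runs.

## Synthetic cohort model

The generator produces the statistical structure the analysis assumes, with
known ground truth, so that every downstream stage can be validated offline.

**Counts.** For gene *g* in sample *s*,

```
E[count_gs] = libsize_s · p_gs ,
p_gs ∝ Σ_c π_sc · μ_gc · 2^(effects applied to s)
```

where `π_s` is the sample's mixture over five cell types (basal, luminal,
stromal, immune, endothelial) and `μ_gc` is the cell-type expression
profile. Counts are negative-binomial via a gamma–Poisson draw with
gene-wise dispersion α (variance `μ + αμ²`), the standard bulk RNA-seq
noise model. Baseline means are log-normal across genes
(`ln mean = ln 50, σ = 1.5`), cell-type factors log-normal (`σ = 0.35`),
dispersions log-normal (`ln α ~ N(ln 0.05, 0.5)` — median α 0.05, typical
of well-powered bulk cohorts), library sizes log-normal around 30 million
so the 15-million QC rule is meaningful.

**Mixtures.** Cancer samples (and occult non-cancer samples, below) draw
`π_s` from a luminal-heavy "tumour" Dirichlet (1.5, 10, 2.5, 2, 1); the
rest from a stromal-leaning "benign" Dirichlet (3, 4, 6, 4, 2). These
defaults give realistic, partially overlapping compositions; analyses that
presume well-separated profiles (occult recovery) use a documented
stronger separation.

**Markers.** Each panel marker's own-cell-type mean is elevated 8× —
enough for mean-of-markers scores to track mixtures, small enough to keep
counts realistic. The tumour-score markers AMACR/PCA3/HOXC4/HOXC6 are
always spiked as cancer-upregulated (FOLH1 tracks the luminal mixture), so
the tumour-content score has a defined signal.

**Spiked effects.** Configurable fractions of the unnamed genes receive
signed log2 shifts: ancestry (default 10% of the pool at 1.0 log2 units,
applied to African samples), cancer status (5% at 1.5, applied to
tumour-regime samples) and PSA group (5% at 1.0, applied to samples above
their ancestry's PSA median). The magnitudes are a design choice — chosen
so recovery tests are informative — not an empirical claim about real
effect sizes, which are unknown for this contrast.

**Occult disease.** A configurable fraction of non-cancer samples keeps the
non-cancer label in the metadata but draws the tumour mixture, the cancer
effects and the cancer PSA distribution. This is the construct the
PSA-high clustering analysis probes.

**PSA.** Log-normal per `ancestry:status` group with configurable medians
(defaults 11.8 / 14.4 / 4.4 ng/mL for African cancer / African non-cancer /
European cancer; σ_log = 0.6), so elevated PSA in non-cancer African
samples — the clinical puzzle motivating the PSA-stratified analyses — is
reproduced.

**Randomness.** All draws derive from `seed` through two child streams:
gene-level (baseline, profiles, dispersions, effect assignment) and
sample-level (occult flags, mixtures, pathology flags, library sizes, PSA,
counts), in that documented order. `noise_seed` re-seeds only the
sample-level stream, which is how twin cohorts sharing gene-level truth but
with independent noise are built for concordance experiments.

**What it does not emulate.** No batch effects or RUV-style unwanted
variation, no transcript-level or read-level structure, no gene–gene
correlation beyond the shared mixtures, no covariate confounding. Passing
tests therefore demonstrate correctness of the pipeline's machinery under
its stated model, not performance on any real cohort.

## QC and normalisation

"Effective library size" is read as the column sum of counts (the term is
not otherwise defined); the sample rule is `libsize ≥ 15e6` **and**
`#{genes with count ≥ 10} ≥ 10,000`, with a removal report that
deduplicates samples failing both. Gene prevalence filtering keeps genes
with count ≥ 10 in ≥ 26 samples (boundary inclusive; 26 = smallest
biological group, so group-private genes can survive); the
small-validation-cohort variant removes genes with ≤ 10 reads in **more
than** 13 samples.

Expression is `log2(count / sf + 1)` with median-of-ratios size factors
over the genes positive in every sample, rescaled to geometric mean 1;
when no such gene exists the fall-back is column-sum scaling with a logged
warning. A variance-stabilising transform is deliberately not used: every
downstream scoring formula is stated on mean log2 expression, so the
simpler transform is the faithful substrate.

PSA ties at the ancestry median go to "low" (`high ⇔ PSA > median`), which
reproduces the odd-n strict-greater split (59 known values → 29 high /
30 low). MAD gene selection uses the raw median absolute deviation (no
consistency constant — only ranks matter) with lexicographic tie-break.

## Differential expression

Per gene, on size-factor-normalised counts: group means `m_A, m_B`, log2
fold change `log2(m_B / m_A)` (pseudocount 0.5 on both means only when one
is zero), and a Wald statistic `lfc / se` with the delta-method standard
error

```
se² = [ (m_A + α m_A²)/(n_A m_A²) + (m_B + α m_B²)/(n_B m_B²) ] / ln²2 .
```

The dispersion α entering the Wald variance is pooled from *within-group*
moments (residual variance after removing group means), so a genuine group
effect does not inflate its own null variance; the standalone
`estimate_dispersion` keeps the plain overall-moments definition
`α = max((s² − μ̄)/μ̄², 1e-8)`. P-values use a two-sided normal reference
and BH adjustment (step-up, NaN-aware).

Known deviations from heavier DE machinery, accepted by design: no
fold-change shrinkage (significance is `padj < 0.05` alone), no
dispersion-trend shrinkage, no independent filtering, no outlier
replacement, single-factor contrasts only (the PSA-high/low contrast is
unadjusted for cancer status). The engine's contract is behavioural:
measured type-I error 0.04–0.06 on null cohorts, ≥ 80% recovery of
2-log2-unit spikes at n = 34 vs 47 with |log2FC error| well under 0.5, and
exact sign antisymmetry. A cross-check against an independently fitted NB
GLM (pydeseq2) on a small cohort requires log2FC correlation > 0.95.

## Enrichment

**Preranked GSEA.** Genes are sorted by the DE Wald statistic (signed,
variance-scaled; ties broken by gene ID for determinism). The running sum
gains `|stat|^w / Σ_set |stat|^w` (default w = 1) at members and loses
`1/(N − |set|)` otherwise; ES is the extremum of largest magnitude (ties
prefer the positive side), and the leading edge is the members at or
before the extremum (at or after, for negative ES). The null permutes gene
labels: one shared pool of without-replacement position subsets (drawn
once per call from the seed, so results do not depend on pathway order);
`p = (1 + #{|ES_perm| ≥ |ES|, same sign}) / (1 + #same-sign)` with floor
`1/(n_perm+1)`, and `NES = ES / mean |ES_perm, same sign|` (undefined and
reported missing when no same-sign permutation exists). Sets are
intersected with the ranking; sizes outside `[min_size, max_size]` or
covering the whole list are skipped with a warning. Permutation p-values
are validated against exhaustive subset enumeration on small instances.

**ORA.** Upper-tail hypergeometric on the overlap between a selected gene
list and each set, within the universe of genes that passed prevalence
filtering (the DE-tested set); BH across reported sets. The selected list
is a per-call parameter (e.g. adjusted-significant downregulated genes, or
nominally significant upregulated ones), since both conventions are in
common use.

**Per-sample scores.** A rank-based single-sample statistic standing in
for kernel-CDF GSVA: within each sample, position *i* of the descending
expression ranking carries weight `(N − i)^0.25`, and the score is the
mean difference between the weighted cumulative in-set fraction and the
uniform out-of-set fraction. It is invariant to any strictly increasing
transform of a sample's expression; analyses built on it use ordering and
correlation properties only, never GSVA-exact values.

## Cell-type scores and tumour content

Signature score = mean log2 expression of a panel's detected markers.
"Detected" defaults to surviving QC (a filtered gene is undetected), with
an optional explicit mean-expression threshold; an undetected marker is
dropped panel-wide with a logged note and reported coverage. Group
comparisons use the two-sided Wilcoxon rank-sum test (exact for combined
n ≤ 20 without ties, tie-corrected normal approximation otherwise).

The tumour-content score is `z(t) − z(b)` across samples, where `t`/`b`
are the per-sample means of the five tumour and three basal markers; z
uses the sample standard deviation and maps a zero-variance vector to all
zeros. The published formula's typography ("FOLH15", "KRT143") is read as
plain means over the five tumour and three basal markers. FOLH1
intentionally appears in both the luminal panel and the tumour score.
Quartile classes use linear-interpolation quantiles of the
cancer-diagnosed reference subset (≥ 4 samples), with left-closed bins and
an inclusive top bin (`score ≥ Q3 → very high`); z-scaling is per-dataset
when external cohorts are scored.

## Clustering and composition

Sample dissimilarity is `1 − Spearman ρ` between cell-type score profiles,
computed after z-scoring each cell type across the clustered samples (the
open choice between raw and standardised scores is resolved toward
standardised, so panels with systematically higher scores do not dominate
every sample's internal ranking); a constant profile gets the maximum
dissimilarity 2 with a warning. Agglomeration is Ward's minimum-variance
method applied to this non-Euclidean dissimilarity — the common
heatmap-package practice — cut at k clusters, with cluster IDs relabelled
by first appearance so assignments are order-stable.

The cancer-like cluster is the one with the higher mean luminal z-score;
the occult-disease fraction is the share of non-cancer samples assigned to
it (undefined when the subset has no non-cancer samples). The dominant
cell type is the argmax of per-cell-type z-scores (so panels of different
marker counts are comparable), ties broken by fixed panel order
(basal, luminal, stromal, immune, endothelial). The flow table is the
three-way count over PSA group × dominant cell type × diagnosis, with
PSA-unknown samples tallied separately.

## Concordance

Discovery genes at `padj < α` (default 0.05) are classified against a
validation cohort: absent (failed the validation cohort's filter), else by
strict sign match of log2FC (zero counts as discordant) and validation
significance. Percentages are reported against the present-in-validation
denominator, with the discovery denominator alongside. Pathway validation
requires validation significance with matching NES sign; fold-ratio
summaries round to one decimal. log2FC concordance uses Pearson
correlation over non-absent genes.

## Problem sizes and defaults

The generator's default cohort mirrors a realistic post-QC design — 34
African cancer, 26 African non-cancer, 47 European cancer — at 2,000 genes,
a deliberate desk scale at which all calibration suites (2,000-gene null
type-I, three-seed power and occult-recovery runs, 1,000-vector BH oracle,
8,000-permutation GSEA enumeration check) complete in seconds while
remaining statistically informative. The full-transcriptome QC defaults
(15M library size, 10,000 expressed genes, 26-sample prevalence) presume
full-transcriptome matrices; call sites on synthetic data pass thresholds
matched to the simulated gene count.

## Known limitations

* DE numerics are intentionally not DESeq2-identical (no shrinkage, simpler
  dispersion); only behavioural properties are guaranteed.
* The GSEA null is gene-permutation (fgsea-simple style); very small
  p-values are floored at `1/(n_perm+1)` rather than estimated by
  multilevel splitting.
* Per-sample enrichment is an ssGSEA-style substitute, not GSVA.
* The generator's independence assumptions (no batch structure, no
  gene–gene correlation beyond mixtures) make synthetic power estimates
  optimistic relative to real cohorts.
* Ward linkage on a correlation dissimilarity is a pragmatic convention,
  not a metric-space guarantee.
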