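# Methods

`cistrans` implements the statistical core of an integrative regulatory-
genomics workflow: linking a transcription factor's genomic binding
(cistrome) to its transcriptome, quantifying how knocking the factor down
reshapes a hormone-driven expression program, mining enrichment results for
keyword meta-groups, screening tumor cohorts for outlier genes and survival
associations, and measuring how a miRNA's expression level re-wires
correlation structure along its target axis. All procedures operate on
plain-text tables (TSV/BED/GMT) and are exercised end-to-end on synthetic
cohorts with planted effects.

## Statistical procedures

### Peak-to-TSS annotation and overlap significance

Peaks are BED-style 0-based half-open intervals; TSS positions are 1-based
and converted on use. The distance between a peak and a TSS is an interval
gap: 0 when the TSS base lies inside the peak, otherwise the number of bases
separating the TSS base from the nearest peak edge. A (peak, gene) pair is
reported when that gap is at most the window (default 7,500 bp, i.e. a
symmetric ±7.5 kb window around the TSS). Strand is used only to sign the
reported distance (positive = peak downstream of the TSS on the gene's
strand); the window itself is symmetric.

Overlap between two peak sets counts the intervals of set A lying within
`max_gap` bp (default 500) of any interval of set B, each counted once.
Significance is an upper-tail hypergeometric test on a binned-genome model:
the universe is a caller-supplied bin count (a reasonable default being
genome length divided by the median peak width), with |A| draws and |B|
successes. The universe is exposed as a parameter because overlap p-values
are only meaningful relative to an explicit background model. Some published
analyses use a 100 bp gap for histone-mark comparisons; `max_gap` covers
both conventions.

### Bootstrap cistrome–transcriptome association

To test whether genes near binding sites respond more strongly to a
perturbation than chance predicts, the observed statistic is the mean
|log2FC| (or signed mean) of the annotated gene set in a differential-
expression table. The null is built by sampling, with replacement, gene
sets of the same size from the full DE universe (default 100,000
resamples). The empirical p-value uses add-one smoothing,
p = (1 + #{null ≥ observed}) / (1 + B), so it is never exactly zero and is
monotone non-increasing in the observed statistic. The same machinery
drives the miRNA-set elevation test (is a candidate miRNA set more elevated
in tumors than random same-size sets?).

### Response-modulation (dampening) classification

Two DE tables share a gene universe: hormone-vs-vehicle in control cells
and in knockdown cells. DEGs are called at linear fold change ≥ 1.2
(boundary inclusive, |log2FC| ≥ log2 1.2) and BH-adjusted p < 0.05 (boundary
exclusive, matching the usual "p.adj < 0.05" convention). The DEG universe
for modulation is the control DEGs. Per gene, the interaction statistic

    z = (lfc_ctl − lfc_kd) / sqrt(SE_ctl² + SE_kd²)

is tested two-sided against a standard normal and BH-adjusted across the
universe. Categories:

* **dampened_induction / dampened_repression** — significant interaction,
  same effect sign, |lfc_kd| < |lfc_ctl| (a significant same-sign reduction
  that falls below the DEG fold threshold still counts as dampened when the
  gene remains a knockdown DEG);
* **lost** — significant interaction with a sign flip, or the knockdown
  effect collapses below the fold threshold;
* **gained** — DEG in knockdown only (capacity change);
* **unchanged** — everything else. A gene whose knockdown response is
  *amplified* is deliberately reported as unchanged with negative delta;
  the classification targets loss of sensitivity.

The source analyses state only that the mean log fold change was compared
between states; the pooled-SE interaction z-test is this package's
operationalization — it is standard, reduces to a comparison of means in
expectation, and has calibrated type-I error under the no-dampening null
(verified by simulation). The summary reports per-category counts, the
dampened fraction of the universe, a hypergeometric enrichment p for
modulated genes among control DEGs, and a sign test for directional
consistency (significant interactions being predominantly magnitude
reductions).

The 2^−ΔΔCt utility implements relative qPCR quantification: ΔCt = Ct(target)
− Ct(reference) per condition, ΔΔCt = ΔCt(experimental) − ΔCt(control),
fold change = 2^−ΔΔCt.

### Keyword meta-group mining

Gene-set names are tokenized by upper-casing and splitting on underscores;
collection prefixes and connective tokens (HALLMARK, KEGG, GOBP, OF, VS, …)
are dropped, while direction suffixes (UP/DN) are kept because they carry
meaning. Sets passing NES > 1.8 and FDR q < 0.05 (both strict) are
"enriched". Per keyword the test is upper-tail hypergeometric (N = all
sets, K = sets carrying the keyword, n = enriched sets, k = enriched sets
carrying it), BH-adjusted across keywords; keywords seen fewer than
`min_count` (default 2) times are dropped before adjustment to limit
multiplicity. The stop-token list is configurable since no canonical
tokenizer exists for set names.

### Tumor/normal Z scores, outlier filter, clustering, survival

Z[g, s] = (x[g, s] − mean_normals(g)) / sd_normals(g) (sd with ddof = 1;
at least two normals required; zero-SD genes are flagged and excluded). The
outlier filter keeps genes with |Z| > 2 in strictly more than 35% of tumors
(both thresholds configurable; 45% is a common stricter variant). Both
inequalities are strict, so a gene at exactly the fraction boundary is
excluded.

Samples are clustered on the filtered genes by agglomerative hierarchical
clustering (Ward linkage on Euclidean distances of per-gene standardized
expression by default; configurable). Cluster–grade association is
reported two ways, because "chi-squared adjusted for age" is not a single
well-defined procedure: an unadjusted chi-squared contingency test of
cluster × (Gleason sum > 7), and a logistic-regression likelihood-ratio
test of the cluster terms on top of an age covariate.

The survival screen uses disease-free survival (time to biochemical
recurrence). In per-gene mode each gene is split at its cohort median
(quartile splits are available via the stratification utility); in
per-cluster mode each cluster is contrasted with the rest. Per unit it
reports the log-rank p, a Cox proportional-hazards HR with 95% CI
(optionally age-adjusted), BH adjustment across units at padj < 0.1, and
Kaplan–Meier curve coordinates for export. Units with no events or an arm
smaller than 2 are flagged inestimable rather than raising. An optional
horizon (e.g. 60 months) censors later events to mirror 5-year recurrence
analyses.

### miRNA axis statistics

* **Consensus targets**: a (miRNA, gene) interaction is kept when at least
  5 of 9 prediction algorithms vote for it (both numbers configurable).
* **Pulldown targetome**: a gene is a direct target when enriched in the
  targeting-mimic pulldown over input (linear FC > 1.2 strict, padj < 0.05)
  and *not* enriched by the same rule in the non-targeting control pulldown.
* **Quartile stratification**: the lower/upper strata are the floor(n/4)
  samples with smallest/largest marker expression, ties broken by stable
  sample order. (Published cohort counts such as 123/122 of 498 imply
  sample exclusions that are not reconstructable; this package uses the
  deterministic floor(n/4) rule.)
* **Correlation shift**: within each stratum, Pearson r of every dependent
  gene against the network gene, two-sided t-distribution p, BH within
  stratum. Genes significant (q < 0.1) in at least one stratum are kept and
  classified by delta = r_low − r_high: *switched* (sign flip, both strata
  significant), *strengthened* (|r_low| > |r_high|), *weakened*
  (|r_low| < |r_high|), else *unchanged*. The classification boundaries are
  this package's documented defaults; the original description leaves them
  under-specified. The Welch two-sample t-test compares correlation
  strengths of the positive-strengthened group vs the negative-weakened
  group, on raw r in the low stratum by default or on Fisher-z transformed
  r. Fewer than two genes in either group flags the test inestimable
  (under a complete null with BH filtering this is the typical outcome, so
  the realized type-I rate is far below nominal).
* **Axis differential expression**: per-gene Welch t on log2 expression
  between two disjoint sample groups with BH adjustment. The output schema
  matches the DE tables consumed elsewhere, so DEG calling and modulation
  classification compose directly. A count-model fit (negative binomial)
  would be the natural choice for raw RNA-seq counts; since the package's
  inputs are continuous log2 matrices, the Welch t is used instead — a
  documented divergence.
* **Correlation matrix**: pairwise Pearson r over shared samples with unit
  diagonal and BH q-values on the off-diagonal entries; zero-variance
  features yield flagged NaN entries.

## Synthetic-data generators

The generators emulate the structure of a prostate-cancer expression cohort
(tumors with normals, miRNA profiles, Gleason grade, disease-free survival)
and of knockdown/hormone experiments, at desk scale and with known ground
truth.

* **Expression model**: log2-scale values from a Gaussian latent model —
  per-feature baseline ~ N(8, 2), sample noise SD 1.0 by default.
  Correlations are planted by mixing a standardized shared factor:
  g = μ + σ(r·z_m + sqrt(1−r²)·ε), so the planted r is the population
  within-stratum Pearson correlation. Axis targets are planted separately
  in the lower and upper miRNA-expression quartile strata (middle samples
  get the mean of the two r values). Several axis groups may be planted to
  carry both correlation signs.
* **Outliers**: planted genes are shifted by z_effect × noise_sd in a
  random tumor subset of the stated fraction, so their tumor-normal Z
  scores exceed the effect size minus noise.
* **Survival**: exponential event times with baseline rate 1/24 per month
  and hazard multiplied by the planted ratio in a marker-defined subgroup
  (subgroup genes shifted by 3 SD so clustering and median splits can
  recover it; the split misclassification of ~6% slightly attenuates
  recovered hazard ratios, which is expected behavior, not a defect).
  Administrative censoring at a horizon solved numerically so the overall
  event fraction matches the requested value. Gleason sums are drawn with a higher
  P(> 7) inside the subgroup, enabling the cluster–grade association test.
* **Knockdown experiment**: responsive genes get hormone log2FC with random
  sign and magnitude max(0.5, N(1.5, 0.3)); a stated subset has the effect
  multiplied by the dampening factor in the knockdown conditions only.
  Replicate values (default triplicates, residual SD 0.1) are summarized to
  per-contrast tables with Welch SE, t p-values and BH adjustment —
  the same schema as real DE tables.
* **Cistrome**: 4 chromosomes × 50 Mb with 1,000 genes by default (~1 TSS
  per 200 kb, human-like density — at much higher density random peaks
  annotate a large share of the gene universe, which no real genome does).
  Every planted bound gene receives one peak within the window of its TSS;
  remaining peaks are uniform. Bound genes' log2FC gets a ±bound_effect
  uplift.
* **Gene sets**: names are underscore-joined tokens sampled from a keyword
  vocabulary plus a unique suffix; the planted keyword enters enriched-set
  names at the enrichment rate and background names at the background rate.

Every generator is deterministic given the spec's seed (byte-identical
serialized output), and all outputs round-trip through the package's
readers/writers.

What the generators do **not** emulate: count-level noise (negative
binomial dispersion), normalization artifacts, batch effects, copy-number
or methylation structure, read-level data, or realistic gene-gene
correlation networks beyond the planted effects. Passing tests therefore
demonstrate that the procedures recover planted effects under a clean
Gaussian model with calibrated error rates — not that they are robust to
every pathology of real cohort data.

## Numerical choices and problem sizes

* Empirical p-values use (1+b)/(1+B); default B = 100,000 (an empirical p
  of 1e−5 requires at least that many resamples); a minimum of 1,000 is
  enforced. Resampling is chunked to bound memory.
* BH adjustment via statsmodels `fdr_bh` throughout; correlation p-values
  from the t-distribution with n−2 df.
* Quartile and median splits break ties by stable sample order; clustering
  is deterministic given distance, linkage and input order.
* Degenerate inputs prefer flags over exceptions where a screen should
  continue (inestimable survival units, zero-variance features); spec
  violations (too few samples, invalid thresholds, non-disjoint groups)
  raise with the offending field named.
* The test suite and acceptance script run recovery simulations at
  moderated sizes chosen to keep the full run within a few minutes on one
  CPU (e.g. 30 power seeds and 100 null seeds for the correlation shift,
  50 survival simulations, 50 null seeds for dampening); the estimated
  quantities are stable at these sizes and the code paths are identical at
  larger ones.

## Known limitations

* The interaction z-test treats per-contrast SEs as known; with very few
  replicates a moderated or t-based test would be more conservative.
* The overlap-significance bin model ignores interval length heterogeneity
  and genomic structure (GC, mappability); its p-values are comparative,
  not calibrated against real genome backgrounds.
* Per-gene survival screening at the median split discards dose
  information; quartile splits or continuous Cox terms are available but
  not the default.
* The correlation-shift class boundaries and the Welch grouping are
  reasonable defaults for an under-specified procedure; alternative
  conventions (significance in both strata, Fisher-z) are exposed as
  options rather than silently chosen.
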