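# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the known limitations of the pipeline.

## Count model and testing

Counts are modeled as negative binomial with a log link,
`Var(K) = mu + alpha * mu^2`, and the log median-of-ratios size factor as
offset, so the coefficients describe relative expression after depth
correction. Fitting is iteratively reweighted least squares, batched across
genes (one shared design matrix, per-gene weights), converging when the
largest coefficient change drops below 1e-8 or after 100 iterations; linear
predictors are clipped to ±30 on the natural-log scale to keep exponentials
finite, and a 1e-10 ridge stabilizes the normal equations. Coefficients are
estimated on the natural-log scale and reported as log2 fold changes
(`beta / ln 2`), with the standard error rescaled the same way so the Wald
statistic `log2fc / se` equals `beta / se_ln`. Two-sided p-values use the
standard normal reference; with 58–74 samples this is adequate, but it is
mildly anticonservative at small n (see calibration below). Genes with
all-zero counts in the contrast samples are flagged and assigned
log2fc = 0, p = 1; non-converged genes are flagged and retained.

### Design matrices

The contrast indicator codes the test group against the reference
(log2FC is test over reference, e.g. NAT over N). Covariates: sex and LT as
0/1 indicators (LT "NA" — the control samples, which have no thyroid
disease — is coded LT−), age centered and scaled to unit variance with
missing values mean-imputed under a warning. Paired comparisons add one
indicator per patient and are restricted, with a warning, to patients with
both arms present (the emulated design pairs only 16 of 46 NAT patients).
Covariates constant within patients are aliased with the patient block and
dropped automatically; a rank deficiency that involves the contrast itself
is an error.

### Dispersion estimation

Per-gene dispersion is estimated by the Pearson chi-square moment condition
around design-fitted means: solve `sum((y - mu)^2 / (mu (1 + alpha mu))) =
n - p` for `alpha >= 0` by bisection, refitting the GLM once at the
estimated dispersions. Estimating around fitted (rather than pooled) means
matters: pooled moments absorb patient and covariate variance into alpha,
which both miscalibrates the test and erases the advantage of a paired
design. A mean–dispersion trend is fitted by Huber-robust regression of log
dispersion on log mean, and estimates are shrunk toward it on the log scale
with weight 0.5 (configurable; 0 = raw moments, 1 = pure trend). Floor
1e-8, ceiling 10. When no design is available the estimator falls back to
the classic pooled moments `(s^2 - mean) / mean^2`.

### Multiple testing and permutation null

BH adjustment is the standard step-up procedure (sort, `p_(i) * m / i`,
cumulative minimum from the largest rank, cap at 1). The permutation null
permutes tissue-group labels among the contrast samples only — covariates
stay attached to their samples, because the null hypothesis is "no group
effect given covariates". Paired designs swap the two labels within each
pair independently with probability 1/2. Dispersions are frozen at their
observed estimates across permutations (re-estimation is available behind a
flag); each permutation draws from a generator stream spawned from the root
seed, so any single permutation is reproducible in isolation. The
permutation p-value uses the add-one convention and is therefore never 0;
per-gene scope is the default, a pooled scope (all genes × all
permutations as one null) is selectable.

## Filtering, DEG calling and trajectories

A gene is filtered out when, in **every** tissue group, more than 25% of
samples have a zero count (`zero_rule="any"` selects the one-group
reading), or when its mean raw count over all samples is below 10 (strictly;
a mean of exactly 10 survives). DEG thresholds: |log2FC| >= log2(1.5)
(inclusive), BH p < 0.05 and permutation p < 0.05 (both strict). The sex
screen contrasts males against females within NAT with age and LT as
covariates and uses the raw p-value at 0.05, deliberately permissive since
it feeds an exclusion filter.

Trajectory arms are classified with the conventional rounded threshold
0.584 on |log2FC| (a flag switches to the exact log2(1.5) = 0.58496; genes
between the two values are vanishingly rare but the choice is explicit) and
the BH-adjusted p by default, for consistency with how the classified genes
were called. Genes absent from the second arm's table (e.g. filtered out of
the paired subset) are excluded with a report, not called "stable": absence
of evidence is not evidence of stability.

## Clustering and PCA

UPGMA (unweighted average linkage) over Euclidean distances is implemented
with an explicit merge history; ties in the minimum inter-cluster distance
break on the lexicographically smallest cluster-id pair, making the
dendrogram deterministic. Cutting at k clusters applies the first n − k
merges (heights are monotone for average linkage on a metric). Sample-level
clustering and PCA operate on log2(normalized + 1); DEG heatmap clustering
operates on row-standardized values, with the population (divide-by-n) SD
convention — the choice is arbitrary but pinned for testability, and
`ddof=1` is available. PCA centers genes, decomposes by SVD and fixes each
component's sign so its largest-magnitude loading is positive.

## Synthetic data generator

Defaults emulate the modeled study design: 12 N, 46 NAT (21 LT+, 37 F / 9 M
scaled), 16 T paired with the first 16 NAT patients (sharing sex, age and
LT status), ages ~ N(48, 12) clipped to [18, 85]. Gene baselines are
log-normal (log-mean 3.5, log-sd 1.8, natural scale), chosen so roughly a
quarter of genes fall under the low-expression filter and the filter is
genuinely exercised; dispersions are gamma(2, 0.05) (mean 0.1); size
factors log-normal with sd 0.3. Planted structure:

* 25 genes per trajectory pattern (150 total) with |log2FC| = 1 per moving
  arm — comfortably above the 0.584 calling threshold, i.e. a detectable
  effect a cohort of this size is powered for;
* 30 sex-biased genes in three equal groups: Y-like (female mean scaled to
  1% — near-zero expression in females), X-like (female-biased, +1 log2)
  and autosomal (±1 log2, random sign);
* 60 LT-responsive genes (±1 log2 in LT+ samples only);
* gene-specific per-patient intercepts (log2-scale normal, sd 0.3) shared
  by both members of a tumor/adjacent pair. These represent between-subject
  biological variability; an intercept uniform across genes would be
  indistinguishable from sequencing depth and absorbed by size factors.

Effects are planted only on genes with baseline mean >= 20 so the planted
truth is not silently removed by the expression filter. All draws flow from
one root generator seeded by the single config seed. The null wrapper
zeroes the trajectory effects while preserving sex, LT, patient and depth
structure, so type-I-error runs exercise covariate adjustment on realistic
heterogeneity.

What the generator does **not** emulate: batch effects beyond library
depth, gene–gene correlation, isoform structure, zero inflation beyond the
NB, GC/length biases, or the empirical moments of any real cohort. Passing
calibration on these simulations shows the engine is internally correct
under the NB model with covariates, not that real thyroid data satisfy
that model.

## Calibration and problem sizes

The acceptance script and test suite measure, at desk scale chosen to keep
a full run around half a minute: type-I error on pure-null data (2000
genes, 30 vs 30, three seeds) for the Wald p and (1000 genes, B = 200) for
the permutation p; log2FC recovery error at 40 vs 40 (genes with mean
normalized expression above 50); and DEG sensitivity, false-discovery
proportion and per-class trajectory recall on the default 12/46/16 design
with B = 200. Trajectory recall is reported over genes that received a
trajectory call: detection loss is already measured by sensitivity, and
compounding the two would count each miss twice. The Wald test runs
slightly hot (~0.055–0.065 at nominal 0.05 with 60 samples), the expected
behavior of a plug-in-dispersion Wald test on NB mixtures; the permutation
p is the assumption-light guard against exactly this.

## Known limitations

* No fold-change shrinkage (apeglm-style) and no likelihood-ratio test in
  the public API (an LRT exists only as a test oracle); numeric parity with
  any specific DE tool is not a goal — validation is by simulation
  calibration and oracle equivalence.
* No outlier handling (no Cook's-distance replacement) and no independent
  filtering: every gene that survives the expression filter gets a p-value.
* The paired analysis uses fixed patient effects, not a mixed model; with
  16 pairs this costs little, but it does not generalize to designs with
  very many small blocks.
* t-SNE is not provided; PCA and UPGMA cover the structure summaries, and
  off-the-shelf embedding libraries can be applied to the normalized
  matrix directly.
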