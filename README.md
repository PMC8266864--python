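# natraj

Differential-expression analysis for three-group thyroid RNA-seq designs:
histologically **n**ormal thyroid (N), normal-appearing **t**umor-**a**djacent
tissue (NAT) and papillary thyroid carcinoma tumors (T), with tumors paired to
a subset of the NAT patients. The package is aimed at transcriptomics analysts
who want the full pipeline of such a study — gene filtering, normalization,
covariate-adjusted negative-binomial testing, permutation-based significance,
sex-bias exclusion, expression-trajectory classification and clustering
summaries — as tested, reusable library code, together with a synthetic count
generator so every stage can be exercised and calibrated without access to
patient data.

## The model

For gene *g* in sample *s* with library size factor *s_s* (median-of-ratios),
counts are modeled as negative binomial,

    K_gs ~ NB(mu_gs, alpha_g),        Var(K) = mu + alpha * mu^2
    log mu_gs = log s_s + x_s' beta_g

where the design row *x_s* holds an intercept, the tissue-group contrast and
covariates (age, sex, lymphocytic thyroiditis); paired tumor-vs-adjacent
comparisons add one indicator per patient. The contrast coefficient is tested
with a Wald statistic beta / SE(beta) against the standard normal, p-values
are Benjamini–Hochberg adjusted across genes, and an empirical null from
label permutations supplies a second, assumption-light p-value
(add-one convention, p >= 1/(B+1)). A gene is called differentially expressed
when |log2FC| >= log2(1.5), BH p < 0.05 and permutation p < 0.05; genes with a
male-vs-female difference (raw p < 0.05) among NAT samples are removed.
Called DEGs are classified along N → NAT → T into six patterns
(up-up, up-stable, up-down, down-down, down-stable, down-up), where an arm is
"up" when p < 0.05 and log2FC >= 0.584, "down" when p < 0.05 and
log2FC < −0.584, and "stable" otherwise.

Gene-level dispersions alpha_g are estimated by a Pearson chi-square moment
estimator around design-fitted means and shrunk on the log scale toward a
robust mean–dispersion trend. Sample and gene structure are summarized by PCA
(SVD of the centered log2 expression) and UPGMA hierarchical clustering
(Euclidean distance, average linkage) with Newick export and tree cutting.

## Worked example

```python
import natraj as nj

# a synthetic cohort shaped like the study: 12 N / 46 NAT / 16 paired T
cfg = nj.SimulationConfig(seed=17)
counts, meta, ann, truth = nj.simulate_dataset(cfg)

kept, removed = nj.filter_low_expression(counts, meta)
spec = nj.DesignSpec(test="NAT", reference="N")        # adjusts age, sex, LT
de = nj.run_de(kept, meta, spec)
de["perm_p"] = nj.permutation_pvalues(
    kept, meta, spec, nj.PermutationConfig(n_permutations=200, seed=23),
    observed=de,
)
degs = nj.call_degs(de)
sex = nj.find_sex_biased_genes(kept, meta)
final = nj.apply_sex_filter(degs, sex.index)

arm2 = nj.run_de(kept, meta, nj.DesignSpec(test="T", reference="NAT", paired=True))
table, pattern_counts, _ = nj.classify_trajectories(final, arm2)
print(len(degs), len(final))
print(pattern_counts.to_dict())
```

Output from this exact script:

```
153 142
{'up-up': 25, 'up-stable': 25, 'up-down': 23, 'down-down': 17, 'down-stable': 30, 'down-up': 22}
```

4000 simulated genes shrink to 3009 after the low-expression filter; 153
genes pass the DEG thresholds and 11 are removed as sex-biased (the generator
planted 150 trajectory genes, so sensitivity here is 0.88 with a
false-discovery proportion of 0.07). The six pattern counts partition the 142
classified DEGs according to their planted N → NAT → T trajectories.

The same steps are available from the shell:

```bash
natraj simulate --out-dir data --seed 17
natraj de --counts data/counts.tsv --meta data/metadata.tsv --contrast NAT:N --out de.tsv
natraj permute --counts data/counts.tsv --meta data/metadata.tsv --contrast NAT:N \
    -B 1000 --seed 23 --de de.tsv --out de.perm.tsv
natraj call --de de.perm.tsv --out degs.tsv
```

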