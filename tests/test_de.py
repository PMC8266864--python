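import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import natraj as nj
from natraj.de import _irls_batch, build_design
from natraj.errors import DesignError, ValidationError


def two_group_meta(n1, n2, group1="N", group2="NAT"):
    rows = []
    for i in range(n1):
        rows.append(dict(sample_id=f"a{i}", tissue_group=group1, sex="F",
                         age=50.0, lt_status="NA", patient_id=None))
    for i in range(n2):
        rows.append(dict(sample_id=f"b{i}", tissue_group=group2, sex="F",
                         age=50.0, lt_status="NA", patient_id=None))
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def count_matrix(values, samples):
    values = np.asarray(values)
    return nj.CountMatrix(
        pd.DataFrame(values, columns=samples,
                     index=pd.Index([f"g{i}" for i in range(len(values))],
                                    name="gene_id"))
    )


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert nj.bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_all_ones_and_singleton(self):
        assert nj.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert nj.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            nj.bh_adjust([0.5, 0.0])
        with pytest.raises(ValidationError):
            nj.bh_adjust([0.5, 1.2])

    def test_matches_bruteforce_and_statsmodels(self):
        """BH equals explicit sort + tail-cummin and statsmodels on random vectors."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(1, 60)
            p = rng.uniform(1e-12, 1.0, size=m)
            ours = nj.bh_adjust(p)
            order = np.argsort(p)
            brute = p[order] * m / np.arange(1, m + 1)
            for i in range(m - 2, -1, -1):
                brute[i] = min(brute[i], brute[i + 1])
            expected = np.empty(m)
            expected[order] = np.minimum(brute, 1.0)
            assert np.allclose(ours, expected)
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])

    def test_padj_dominates_pvalue_and_is_monotone(self, sim_filtered):
        kept, meta, *_ = sim_filtered
        de = nj.run_de(kept, meta, nj.DesignSpec(test="NAT", reference="N"))
        assert (de["padj"] >= de["pvalue"] - 1e-12).all()
        ordered = de.sort_values("pvalue")
        assert (np.diff(ordered["padj"].to_numpy()) >= -1e-12).all()


class TestDispersions:
    def test_poisson_gene_hits_floor(self):
        rng = np.random.default_rng(0)
        counts = count_matrix(rng.poisson(100, size=(50, 200)),
                              [f"s{i}" for i in range(200)])
        sf = pd.Series(1.0, index=counts.sample_ids)
        disp = nj.estimate_dispersions(counts, sf, shrinkage=0.0)
        assert (disp < 0.02).mean() > 0.9

    def test_constant_gene_at_floor(self):
        counts = count_matrix([[5] * 10], [f"s{i}" for i in range(10)])
        sf = pd.Series(1.0, index=counts.sample_ids)
        disp = nj.estimate_dispersions(counts, sf, shrinkage=0.0)
        assert disp.iloc[0] == pytest.approx(1e-8)

    def test_recovers_planted_dispersion(self):
        """NB data with alpha = 0.2 at n = 200: mean estimate within [0.15, 0.25]."""
        rng = np.random.default_rng(7)
        alpha, mu, n = 0.2, 200.0, 200
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu), size=(500, n))
        counts = count_matrix(y, [f"s{i}" for i in range(n)])
        sf = pd.Series(1.0, index=counts.sample_ids)
        disp = nj.estimate_dispersions(counts, sf)
        assert 0.15 < disp.mean() < 0.25


class TestFitNBGLM:
    def test_poisson_limit_matches_group_mean_ratio(self):
        y = np.array([10, 12, 8, 30, 28, 32], float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        beta, cov = nj.fit_nb_glm(y, X, np.ones(6), dispersion=1e-10)
        assert beta[0] == pytest.approx(np.log(10), abs=1e-6)
        assert beta[1] == pytest.approx(np.log(30 / 10), abs=1e-6)

    def test_matches_statsmodels_nb_glm(self):
        """Coefficients and SEs agree with statsmodels' NB GLM at fixed alpha."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n, alpha = 60, 0.1
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.integers(0, 2, n).astype(float)])
        mu = np.exp(3.0 + 0.8 * X[:, 1] - 0.5 * X[:, 2])
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu))
        beta, cov = nj.fit_nb_glm(y, X, np.ones(n), dispersion=alpha)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert beta == pytest.approx(ref.params, abs=1e-5)
        assert np.sqrt(np.diag(cov)) == pytest.approx(ref.bse, rel=1e-3)

    def test_offset_equivalence(self):
        """Doubling size factors halves the fitted intercept mean, not the contrast."""
        rng = np.random.default_rng(9)
        y = rng.poisson(50, size=20)
        X = np.column_stack([np.ones(20), rng.integers(0, 2, 20).astype(float)])
        b1, _ = nj.fit_nb_glm(y, X, np.ones(20), 0.05)
        b2, _ = nj.fit_nb_glm(y, X, np.full(20, 2.0), 0.05)
        assert b2[0] == pytest.approx(b1[0] - np.log(2), abs=1e-6)
        assert b2[1] == pytest.approx(b1[1], abs=1e-6)

    def test_recovers_planted_log2fc(self):
        """True log2FC 1.5 at n = 40/group, alpha = 0.1: estimate within 0.25."""
        rng = np.random.default_rng(21)
        n, alpha, lfc = 80, 0.1, 1.5
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 40)])
        mu = 100 * 2 ** (lfc * X[:, 1])
        r = 1 / alpha
        Y = rng.negative_binomial(r, r / (r + mu), size=(200, n)).astype(float)
        beta, cov, conv = _irls_batch(Y, X, np.zeros(n), np.full(200, alpha))
        est = beta[:, 1] / np.log(2)
        assert conv.all()
        assert np.abs(est - lfc).mean() < 0.1
        assert np.abs(est.mean() - lfc) < 0.25


class TestRunDE:
    def test_contrast_orientation_antisymmetry(self, sim_filtered):
        kept, meta, *_ = sim_filtered
        fwd = nj.run_de(kept, meta, nj.DesignSpec(test="NAT", reference="N"))
        rev = nj.run_de(kept, meta, nj.DesignSpec(test="N", reference="NAT"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-6)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-8)

    def test_all_zero_gene_policy(self):
        meta = two_group_meta(4, 4)
        values = np.vstack([np.zeros(8, int), np.full(8, 40, int)])
        de = nj.run_de(count_matrix(values, list(meta.index)), meta,
                       nj.DesignSpec(test="NAT", reference="N", covariates=()))
        assert de.loc["g0", "flag"] == "all_zero"
        assert de.loc["g0", "log2fc"] == 0.0
        assert de.loc["g0", "pvalue"] == 1.0

    def test_single_sample_group_is_design_error(self):
        meta = two_group_meta(1, 5)
        values = np.full((3, 6), 10, int)
        with pytest.raises(DesignError, match=">= 2 samples"):
            nj.run_de(count_matrix(values, list(meta.index)), meta,
                      nj.DesignSpec(test="NAT", reference="N"))

    def test_paired_more_powerful_than_unpaired_with_patient_effects(self):
        """Strong patient intercepts: pairing absorbs them and boosts power."""
        cfg = nj.SimulationConfig(seed=5, patient_effect_sd=1.2,
                                  effect_log2fc=0.7, n_genes=1500)
        counts, meta, _, truth = nj.simulate_dataset(cfg)
        kept, _ = nj.filter_low_expression(counts, meta)
        sig_genes = [g for g in kept.gene_ids
                     if truth.genes.loc[g, "true_log2fc_TvsNAT"] != 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            paired = nj.run_de(kept, meta,
                               nj.DesignSpec(test="T", reference="NAT", paired=True))
            unpaired = nj.run_de(kept, meta,
                                 nj.DesignSpec(test="T", reference="NAT"))
        power_paired = (paired.loc[sig_genes, "padj"] < 0.05).mean()
        power_unpaired = (unpaired.loc[sig_genes, "padj"] < 0.05).mean()
        assert power_paired > power_unpaired

    def test_null_pvalues_uniform(self):
        """KS distance of null Wald p-values from uniform below 0.05."""
        cfg = nj.SimulationConfig(seed=13, n_genes=2500, n_N=30, n_NAT=30, n_T=0,
                                  n_sex_genes=0, lt_effect_genes=0)
        counts, meta, _, _ = nj.simulate_null_dataset(cfg)
        kept, _ = nj.filter_low_expression(counts, meta)
        de = nj.run_de(kept, meta, nj.DesignSpec(test="NAT", reference="N"))
        p = de.loc[de["flag"] == "ok", "pvalue"].to_numpy()
        assert len(p) >= 1500
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_wald_agrees_with_nb_likelihood_ratio_test(self):
        """Wald and a direct NB LRT make the same call on >= 95% of null+signal genes."""
        from scipy.optimize import minimize
        from scipy.special import gammaln

        rng = np.random.default_rng(3)
        n, alpha = 60, 0.1
        group = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([np.ones(n), group])
        lfcs = rng.choice([0.0, 0.0, 0.4, -0.4], size=500)
        mu = 80 * 2 ** np.outer(lfcs, group)
        r = 1 / alpha
        Y = rng.negative_binomial(r, r / (r + mu)).astype(float)

        beta, cov, _ = _irls_batch(Y, X, np.zeros(n), np.full(500, alpha))
        wald_z = beta[:, 1] / np.sqrt(cov[:, 1, 1])
        wald_reject = 2 * stats.norm.sf(np.abs(wald_z)) < 0.05

        def nb_negll(eta):
            m = np.exp(eta)
            return -np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                           + r * np.log(r / (r + m)) + y * np.log(m / (r + m)))

        lrt_reject = np.zeros(500, dtype=bool)
        for g in range(500):
            y = Y[g]
            full = minimize(lambda b: nb_negll(X @ b), x0=beta[g], method="Nelder-Mead")
            null = minimize(lambda b: nb_negll(np.full(n, b[0])),
                            x0=[np.log(y.mean() + 0.5)], method="Nelder-Mead")
            lrt = 2 * (null.fun - full.fun)
            lrt_reject[g] = stats.chi2.sf(max(lrt, 0.0), df=1) < 0.05
        agreement = (wald_reject == lrt_reject).mean()
        assert agreement >= 0.95


class TestBuildDesign:
    def test_aliased_covariate_dropped_in_paired_design(self, sim_default):
        _, counts, meta, _, _ = sim_default
        spec = nj.DesignSpec(test="T", reference="NAT", paired=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = build_design(meta, spec)
        # sex, LT and age are constant within pairs: absorbed by patient block
        assert all(not c.startswith(("sex", "lt", "age")) for c in design.columns)
        assert "tissue_group[T]" in design.columns

    def test_missing_age_mean_imputed_with_warning(self):
        meta = two_group_meta(4, 4)
        meta.loc[meta.index[0], "age"] = np.nan
        values = np.random.default_rng(0).poisson(30, size=(5, 8))
        with pytest.warns(UserWarning, match="mean-imputed"):
            nj.run_de(count_matrix(values, list(meta.index)), meta,
                      nj.DesignSpec(test="NAT", reference="N", covariates=("age",)))
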