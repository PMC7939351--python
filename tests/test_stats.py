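"""Inference tests: Huber RLM + BCa, random-intercept REML + percentile
bootstrap, group tests — each cross-checked against an independent
implementation or known truth."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from isoglyco.errors import DesignError, DomainError
from isoglyco.stats import (
    Contrast,
    _bca_interval,
    bootstrap_quantile,
    bootstrap_lmm_percentile,
    bootstrap_rlm_bca,
    chi_squared_proportions,
    fit_lmm_reml,
    fit_rlm,
    genotype_contrasts,
    genotype_design,
    kruskal_wallis,
    lmm_contrasts,
    wilcoxon_mann_whitney,
)


def _sim_long(rng, n_subj=40, beta_time=2.0, beta_at_time=1.0,
              tau2=1.0, sigma2=1.0, intercept=5.0):
    base = n_subj // 3
    genos = np.repeat(["TT", "AT", "AA"], [n_subj - 2 * base, base, base])
    subj = np.repeat(np.arange(n_subj), 2)
    g = np.repeat(genos, 2)
    t = np.tile([0.0, 1.0], n_subj)
    mean = intercept + beta_time * t + beta_at_time * ((g == "AT") & (t == 1))
    y = mean + np.repeat(rng.normal(0, np.sqrt(tau2), n_subj), 2) \
        + rng.normal(0, np.sqrt(sigma2), 2 * n_subj)
    return pd.DataFrame(dict(subject_id=subj, time=t, genotype=g, value=y))


class TestRLM:
    def test_matches_mass_style_rlm(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = 1 + 2 * x + rng.normal(size=n)
        y[:6] += 15.0
        ours = fit_rlm(X, y)
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad")
        assert np.allclose(ours.coef, ref.params, atol=1e-8)
        assert np.isclose(ours.scale, ref.scale, rtol=1e-6)

    def test_huber_limit_is_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = X @ [1.0, 2.0] + rng.normal(size=50)
        ours = fit_rlm(X, y, c=1e12)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(ours.coef - ols)) <= 1e-8

    def test_resists_gross_outliers_where_ls_fails(self):
        rng = np.random.default_rng(2)
        n = 60
        x = np.sort(rng.uniform(0, 3, n))
        X = np.column_stack([np.ones(n), x])
        y = 2.0 * x + 0.1 * rng.standard_normal(n)
        # 10% gross outliers scattered over the upper half of x
        idx = rng.choice(np.arange(n // 2, n), n // 10, replace=False)
        y[idx] += 40.0
        huber = fit_rlm(X, y).coef[1]
        ls = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert abs(huber - 2.0) < 0.1
        assert abs(ls - 2.0) > 0.5

    def test_constant_response(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        f = fit_rlm(X, np.full(10, 3.3))
        assert np.isclose(f.coef[0], 3.3) and np.isclose(f.coef[1], 0.0)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(DesignError):
            fit_rlm(X, np.arange(10.0))


class TestBCa:
    def test_symmetric_reduces_to_percentile(self):
        u = np.linspace(0.1, 3.0, 250)
        boot = np.concatenate([-u, u])          # symmetric about 0 = theta
        jack = np.zeros(20)                     # zero acceleration
        lo, hi = _bca_interval(0.0, boot, jack, 0.99)
        assert np.isclose(lo, bootstrap_quantile(boot, 0.005))
        assert np.isclose(hi, bootstrap_quantile(boot, 0.995))
        # and the two endpoints are symmetric about the estimate
        assert np.isclose(lo, -hi)

    def test_fixed_seed_bitwise_reproducible(self):
        rng = np.random.default_rng(3)
        genos = np.repeat(["TT", "AT", "AA"], 15)
        X, names = genotype_design(genos)
        y = rng.standard_normal(45)
        f = fit_rlm(X, y)
        cons = genotype_contrasts(f.coef, names)
        a = bootstrap_rlm_bca(f, cons, B=300, seed=11)
        b = bootstrap_rlm_bca(f, cons, B=300, seed=11)
        assert [(c.ci_low, c.ci_high) for c in a] == \
            [(c.ci_low, c.ci_high) for c in b]

    def test_degenerate_distribution_zero_width(self):
        boot = np.full(100, 2.5)
        lo, hi = _bca_interval(2.5, boot, np.zeros(10), 0.99)
        assert lo == hi == 2.5

    def test_sign_flip_negates_and_swaps_interval(self):
        rng = np.random.default_rng(5)
        genos = np.repeat(["TT", "AT", "AA"], 15)
        X, names = genotype_design(genos)
        y = rng.standard_normal(45) + 0.8 * (genos == "AT")
        f_pos = fit_rlm(X, y)
        f_neg = fit_rlm(X, -y)
        c_pos = genotype_contrasts(f_pos.coef, names)[0]
        c_neg = genotype_contrasts(f_neg.coef, names)[0]
        a = bootstrap_rlm_bca(f_pos, [c_pos], B=400, seed=9)[0]
        b = bootstrap_rlm_bca(f_neg, [c_neg], B=400, seed=9)[0]
        assert np.isclose(a.estimate, -b.estimate)
        assert np.isclose(a.ci_low, -b.ci_high, atol=0.15)
        assert a.significant == b.significant


class TestLMM:
    def test_matches_statsmodels_mixedlm(self):
        df = _sim_long(np.random.default_rng(7))
        ours = fit_lmm_reml(df, "value")
        ref = sm.MixedLM.from_formula(
            'value ~ C(time)*C(genotype, Treatment("TT"))',
            groups="subject_id", data=df).fit(reml=True)
        assert np.isclose(ours.tau2, ref.cov_re.iloc[0, 0], atol=1e-4)
        assert np.isclose(ours.sigma2, ref.scale, atol=1e-4)
        assert np.allclose(np.sort(ours.params),
                           np.sort(ref.fe_params.values), atol=1e-6)

    def test_independence_limit_equals_ols(self):
        rng = np.random.default_rng(8)
        df = _sim_long(rng, tau2=0.0)
        fit = fit_lmm_reml(df, "value")
        X = np.column_stack([
            np.ones(len(df)), (df.time == 1.0),
            (df.genotype == "AT"), (df.genotype == "AA"),
            (df.genotype == "AT") & (df.time == 1.0),
            (df.genotype == "AA") & (df.time == 1.0)]).astype(float)
        ols = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)[0]
        assert fit.tau2 < 0.2
        if fit.tau2 == 0.0:
            assert np.allclose(fit.params, ols, atol=1e-6)

    def test_parameter_recovery_over_replicates(self):
        rng = np.random.default_rng(9)
        taus, sigmas, betas = [], [], []
        for _ in range(120):
            df = _sim_long(rng, n_subj=60, tau2=4.0, sigma2=1.0)
            f = fit_lmm_reml(df, "value")
            taus.append(f.tau2)
            sigmas.append(f.sigma2)
            betas.append(f.params[f.names.index("geno[AT]:time[1.0]")])
        # means within Monte-Carlo error of truth
        assert abs(np.mean(taus) - 4.0) < 3 * np.std(taus) / np.sqrt(120)
        assert abs(np.mean(sigmas) - 1.0) < 0.05
        assert abs(np.mean(betas) - 1.0) < 3 * np.std(betas) / np.sqrt(120)

    def test_icc_definition(self):
        df = _sim_long(np.random.default_rng(10))
        f = fit_lmm_reml(df, "value")
        assert np.isclose(f.icc, f.tau2 / (f.tau2 + f.sigma2))
        assert 0.0 <= f.icc <= 1.0

    def test_contrast_telescoping_identity(self):
        df = _sim_long(np.random.default_rng(11))
        f = fit_lmm_reml(df, "value")
        cons = {c.label: c.estimate for c in lmm_contrasts(f)}
        for t in ("0.0", "1.0"):
            assert np.isclose(cons[f"A/T-T/T at {t}"]
                              + cons[f"A/A-A/T at {t}"],
                              cons[f"A/A-T/T at {t}"], atol=1e-12)

    def test_zero_genotype_coefficients_zero_contrasts(self):
        df = _sim_long(np.random.default_rng(12))
        f = fit_lmm_reml(df, "value")
        f.params[2:] = 0.0      # kill genotype and interaction effects
        for c in lmm_contrasts(f):
            assert c.estimate == 0.0

    def test_bootstrap_determinism_and_consistency(self):
        df = _sim_long(np.random.default_rng(13))
        f = fit_lmm_reml(df, "value")
        cons = lmm_contrasts(f)[:2]
        a = bootstrap_lmm_percentile(f, cons, B=400, seed=21)
        b = bootstrap_lmm_percentile(f, cons, B=400, seed=21)
        assert [(c.ci_low, c.ci_high) for c in a] == \
            [(c.ci_low, c.ci_high) for c in b]
        # endpoints converge as B grows (same generator stream)
        small = bootstrap_lmm_percentile(f, cons, B=200, seed=5)
        big1 = bootstrap_lmm_percentile(f, cons, B=4000, seed=5)
        big2 = bootstrap_lmm_percentile(f, cons, B=4000, seed=6)
        gap_small = abs(small[0].ci_low - a[0].ci_low)
        gap_big = abs(big1[0].ci_low - big2[0].ci_low)
        assert gap_big < max(gap_small, 0.3)

    def test_missing_cell_is_reported(self):
        df = _sim_long(np.random.default_rng(14))
        df = df[df.genotype != "AA"]
        f = fit_lmm_reml(df, "value")
        with pytest.raises(DesignError):
            lmm_contrasts(f, genotype_pairs=[("AA", "TT")])


class TestGroupTests:
    def test_kruskal_matches_textbook_formula(self):
        groups = [[2.9, 3.0, 2.5, 2.6, 3.2], [3.8, 2.7, 4.0, 2.4],
                  [2.8, 3.4, 3.7, 2.2, 2.0]]
        allv = np.concatenate(groups)
        order = allv.argsort()
        ranks = np.empty(allv.size)
        ranks[order] = np.arange(1, allv.size + 1)
        # average ties
        for v in np.unique(allv):
            m = allv == v
            ranks[m] = ranks[m].mean()
        n = allv.size
        h = 12.0 / (n * (n + 1)) * sum(
            ranks[sum(len(g) for g in groups[:i]):
                  sum(len(g) for g in groups[:i + 1])].sum() ** 2 / len(g)
            for i, g in enumerate(groups)) - 3 * (n + 1)
        _, counts = np.unique(allv, return_counts=True)
        h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
        stat, _ = kruskal_wallis(*groups)
        assert np.isclose(stat, h)

    def test_identical_groups_null_results(self):
        stat, p = wilcoxon_mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
        stat, p = kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_equal_proportions_zero_chi2(self):
        stat, p = chi_squared_proportions([[10, 20, 30], [20, 40, 60]])
        assert np.isclose(stat, 0.0)
        assert np.isclose(p, 1.0)

    def test_input_validation(self):
        with pytest.raises(DomainError):
            kruskal_wallis([1.0, 2.0])
        with pytest.raises(DomainError):
            wilcoxon_mann_whitney([], [1.0])
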