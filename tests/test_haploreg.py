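"""EM haplotype-specific regression: oracles, invariances, downstream summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm

from cnphap import presets
from cnphap.haploreg import (
    anova_explained,
    enumerate_diplotypes,
    fit_haplo_linear,
    fit_haplo_logistic,
    haplotype_frequencies_em,
    liability_variance,
    lr_test,
)
from cnphap.synthcohort import (
    Haplotype,
    HaplotypeModel,
    collapse_genotypes,
    draw_diplotypes,
    haplotype_universe,
    simulate_quantitative,
)

PHASE_KNOWN_UNIVERSE = (Haplotype("T", 0), Haplotype("T", 1), Haplotype("C", 1))
# every collapsed genotype over these three haplotypes identifies its diplotype


def _phase_known_model(effects=(0.0, 0.0, 0.0)):
    return HaplotypeModel(
        haplotypes=PHASE_KNOWN_UNIVERSE,
        freqs=np.array([0.2, 0.45, 0.35]),
        effects=np.array(effects),
    )


def _counts_matrix(dipl, n_haps):
    out = np.zeros((len(dipl), n_haps))
    np.add.at(out, (np.arange(len(dipl)), dipl[:, 0]), 1)
    np.add.at(out, (np.arange(len(dipl)), dipl[:, 1]), 1)
    return out


class TestEnumerateDiplotypes:
    def test_het_cn2_three_diplotypes(self, universe):
        ds = enumerate_diplotypes(1, 2, universe)
        labels = {
            tuple(sorted((universe[i].label, universe[j].label))) for i, j in ds.pairs
        }
        assert labels == {("C/1", "T/1"), ("C/0", "T/2"), ("C/2", "T/0")}

    def test_hom_ref_cn0_forced(self, universe):
        ds = enumerate_diplotypes(0, 0, universe)
        assert len(ds.pairs) == 1
        assert universe[ds.pairs[0][0]].label == "T/0"

    def test_het_cn1_two_diplotypes(self, universe):
        ds = enumerate_diplotypes(1, 1, universe)
        labels = {
            tuple(sorted((universe[i].label, universe[j].label))) for i, j in ds.pairs
        }
        assert labels == {("C/1", "T/0"), ("C/0", "T/1")}

    def test_matches_brute_force_for_all_classes(self, universe):
        alt = np.array([h.snp_allele == "C" for h in universe], dtype=int)
        cn = np.array([h.hap_cn for h in universe])
        for gt, tcn in itertools.product(range(3), range(5)):
            expected = {
                (i, j)
                for i in range(6)
                for j in range(i, 6)
                if alt[i] + alt[j] == gt and cn[i] + cn[j] == tcn
            }
            ds = enumerate_diplotypes(gt, tcn, universe)
            got = {tuple(p) for p in ds.pairs}
            assert got == expected
            assert ds.inconsistent == (len(expected) == 0)


class TestLinearEM:
    def test_phase_known_equals_ols_and_counting(self, rng):
        """No latent phase: EM equals direct OLS and direct allele counting."""
        m = _phase_known_model(effects=(-4.0, 0.0, -2.7))
        dipl = draw_diplotypes(m, 600, rng)
        y = simulate_quantitative(dipl, m, 5.0, rng)
        gt, cn = collapse_genotypes(dipl, m)
        fit = fit_haplo_linear(
            y, gt, cn, universe=PHASE_KNOWN_UNIVERSE, reference="T/1", tol=1e-12
        )
        counts = _counts_matrix(dipl, 3)
        X = np.column_stack([np.ones(len(y)), counts[:, 0], counts[:, 2]])
        ols = sm.OLS(y, X).fit()
        assert fit.effects[0] == pytest.approx(ols.params[1], abs=1e-8)
        assert fit.effects[2] == pytest.approx(ols.params[2], abs=1e-8)
        assert fit.freqs == pytest.approx(counts.mean(axis=0) / 2, abs=1e-10)

    def test_reference_relabeling_shifts_effects(self, gwas_model, rng):
        dipl = draw_diplotypes(gwas_model, 1500, rng)
        y = simulate_quantitative(dipl, gwas_model, 16.9, rng)
        gt, cn = collapse_genotypes(dipl, gwas_model)
        f1 = fit_haplo_linear(y, gt, cn, reference="T/1", tol=1e-12, compute_se=False)
        f2 = fit_haplo_linear(y, gt, cn, reference="C/1", tol=1e-12, compute_se=False)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-4)
        assert f1.sigma2 == pytest.approx(f2.sigma2, rel=1e-6)
        labels = [h.label for h in f1.universe]
        shift = f2.effects[labels.index("T/1")]
        for i in range(len(labels)):
            if not np.isnan(f1.effects[i]) and not np.isnan(f2.effects[i]):
                assert f1.effects[i] == pytest.approx(f2.effects[i] - shift, abs=5e-3)

    def test_expected_counts_sum_to_two(self, gwas_model, rng):
        dipl = draw_diplotypes(gwas_model, 400, rng)
        y = simulate_quantitative(dipl, gwas_model, 16.9, rng)
        gt, cn = collapse_genotypes(dipl, gwas_model)
        fit = fit_haplo_linear(y, gt, cn, compute_se=False)
        assert np.allclose(fit.expected_haplotype_counts().sum(axis=1), 2.0, atol=1e-9)

    def test_frequency_recovery_unbiased(self, gwas_model):
        """Mean fitted frequencies across replicates within 3 MC SEs of truth."""
        reps = 20
        ests = []
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            dipl = draw_diplotypes(gwas_model, 2000, rng)
            y = simulate_quantitative(dipl, gwas_model, 16.9, rng)
            gt, cn = collapse_genotypes(dipl, gwas_model)
            fit = fit_haplo_linear(y, gt, cn, compute_se=False)
            labels = [h.label for h in fit.universe]
            order = [labels.index(h.label) for h in gwas_model.haplotypes]
            ests.append(fit.freqs[order])
        ests = np.array(ests)
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(reps)
        err = np.abs(ests.mean(axis=0) - gwas_model.freqs)
        assert np.all(err < 3 * mc_se + 1e-4)

    def test_em_matches_multistart_optimizer(self, rng):
        """Small ambiguous cohort: EM reaches the multistart quasi-Newton optimum."""
        uni = (Haplotype("T", 1), Haplotype("C", 1), Haplotype("T", 2), Haplotype("C", 0))
        alt = np.array([0, 1, 0, 1])
        hcn = np.array([1, 1, 2, 0])
        # observed classes incl. the ambiguous (het, cn=2)
        gt = np.array([1, 1, 1, 0, 2, 1, 1, 0, 1, 2, 0, 1])
        cn = np.array([2, 2, 1, 2, 2, 3, 2, 4, 2, 2, 2, 2])
        y = np.array([1.2, -0.4, 0.3, 2.1, -1.5, 0.8, 0.2, 1.9, 0.5, -0.9, 1.4, 0.1])
        fit = fit_haplo_linear(
            y, gt, cn, universe=uni, reference="T/1", tol=1e-13, compute_se=False
        )
        # independent observed-data log-likelihood via brute-force pairs
        compat = []
        for g, c in zip(gt, cn):
            pairs = [
                (i, j)
                for i in range(4)
                for j in range(i, 4)
                if alt[i] + alt[j] == g and hcn[i] + hcn[j] == c
            ]
            compat.append(pairs)

        def negll(theta):
            mu, b1, b2, b3, logs = theta[:5]
            q = theta[5:]
            p = np.exp(np.concatenate([[0.0], q]))
            p = p / p.sum()
            beta = np.array([0.0, b1, b2, b3])
            s = np.exp(logs)
            ll = 0.0
            for yi, pairs in zip(y, compat):
                tot = 0.0
                for i, j in pairs:
                    prior = p[i] * p[j] * (2.0 if i != j else 1.0)
                    tot += prior * norm.pdf(yi, mu + beta[i] + beta[j], s)
                ll += np.log(max(tot, 1e-300))
            return -ll

        best = np.inf
        for k in range(10):
            x0 = np.random.default_rng(k).normal(0, 1, 8)
            res = minimize(negll, x0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-11})
            best = min(best, res.fun)
        assert fit.log_likelihood >= -best - 1e-3

    def test_absent_haplotype_dropped_with_warning(self, rng):
        # all samples are hom-ref: no compatible diplotype carries a C haplotype
        n = 60
        gt = np.zeros(n, dtype=int)
        cn = np.concatenate([np.full(n - 10, 2), np.full(10, 1)])
        y = rng.normal(0, 1, n)
        with pytest.warns(UserWarning, match="dropped"):
            fit = fit_haplo_linear(y, gt, cn, compute_se=False)  # full 6-hap universe
        labels = [h.label for h in fit.universe]
        assert np.isnan(fit.effects[labels.index("C/2")])
        assert np.isnan(fit.effects[labels.index("C/1")])


class TestLogisticEM:
    def test_phase_known_equals_logit(self, rng):
        m = _phase_known_model()
        dipl = draw_diplotypes(m, 1200, rng)
        counts = _counts_matrix(dipl, 3)
        eta = -0.5 - 0.8 * counts[:, 0] + 0.4 * counts[:, 2]
        s = (rng.random(1200) < 1 / (1 + np.exp(-eta))).astype(int)
        gt, cn = collapse_genotypes(dipl, m)
        fit = fit_haplo_logistic(
            s, gt, cn, universe=PHASE_KNOWN_UNIVERSE, reference="T/1", tol=1e-13
        )
        X = np.column_stack([np.ones(1200), counts[:, 0], counts[:, 2]])
        ref = sm.Logit(s, X).fit(disp=0)
        assert fit.effects[0] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.effects[2] == pytest.approx(ref.params[2], abs=1e-6)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)

    def test_null_effects_within_band(self):
        """Zero-effect case-control draw: common-haplotype ORs inside null band."""
        model = HaplotypeModel.from_percent(
            presets.DISEASE_DESIGNS["copd"]["control_freq_pct"],
            odds_ratios={h: 1.0 for h in presets.DISEASE_DESIGNS["copd"]["control_freq_pct"]},
            reference="T/1",
        )
        rng = np.random.default_rng(99)
        dipl = draw_diplotypes(model, 5000, rng)
        s = rng.binomial(1, 0.3, 5000)
        gt, cn = collapse_genotypes(dipl, model)
        fit = fit_haplo_logistic(s, gt, cn, compute_se=False)
        labels = [h.label for h in fit.universe]
        for lbl in ("T/0", "C/1"):
            orr = np.exp(fit.effects[labels.index(lbl)])
            assert 0.85 < orr < 1.18

    def test_single_class_rejected(self, rng):
        m = _phase_known_model()
        dipl = draw_diplotypes(m, 50, rng)
        gt, cn = collapse_genotypes(dipl, m)
        with pytest.raises(ValueError, match="classes"):
            fit_haplo_logistic(np.ones(50), gt, cn, universe=PHASE_KNOWN_UNIVERSE)


class TestGenotypeOnlyEM:
    def test_matches_truth_at_scale(self, gwas_model):
        dipl = draw_diplotypes(gwas_model, 30_000, seed=5)
        gt, cn = collapse_genotypes(dipl, gwas_model)
        p = haplotype_frequencies_em(gt, cn)
        uni = haplotype_universe()
        labels = [h.label for h in uni]
        order = [labels.index(h.label) for h in gwas_model.haplotypes]
        assert np.all(np.abs(p[order] - gwas_model.freqs) < 0.01)


class TestAnova:
    def test_phase_known_matches_direct_ols(self, rng):
        m = _phase_known_model(effects=(-3.0, 0.0, -1.5))
        dipl = draw_diplotypes(m, 800, rng)
        y = simulate_quantitative(dipl, m, 4.0, rng)
        gt, cn = collapse_genotypes(dipl, m)
        fit = fit_haplo_linear(
            y, gt, cn, universe=PHASE_KNOWN_UNIVERSE, reference="T/1", compute_se=False
        )
        rep = anova_explained(fit, y)
        counts = _counts_matrix(dipl, 3)
        Xf = np.column_stack([np.ones(len(y)), counts[:, 0], counts[:, 2]])
        rss_f = np.sum(sm.OLS(y, Xf).fit().resid ** 2)
        rss_n = np.sum((y - y.mean()) ** 2)
        assert rep.explained_fraction == pytest.approx(1 - rss_f / rss_n, abs=1e-10)

    def test_null_effects_small_explained_fraction(self, gwas_model):
        model = HaplotypeModel(
            haplotypes=gwas_model.haplotypes,
            freqs=gwas_model.freqs,
            effects=np.zeros(6),
        )
        rng = np.random.default_rng(7)
        dipl = draw_diplotypes(model, 10_000, rng)
        y = simulate_quantitative(dipl, model, 16.9, rng)
        gt, cn = collapse_genotypes(dipl, model)
        fit = fit_haplo_linear(y, gt, cn, compute_se=False)
        rep = anova_explained(fit, y)
        assert rep.explained_fraction < 0.002


class TestLiability:
    def test_zero_observed_variance(self):
        assert liability_variance(0.0, 0.2).v_liab == 0.0

    def test_half_prevalence_multiplier(self):
        rep = liability_variance(1.0, 0.5)
        assert rep.v_liab == pytest.approx(np.pi / 2, abs=1e-6)

    def test_generative_liability_recovery(self, rng):
        """Simulated liability model (h^2 = 0.3, K = 0.2): transform recovers h^2."""
        n, h2, K = 50_000, 0.3, 0.2
        g = rng.normal(0, np.sqrt(h2), n)
        liab = g + rng.normal(0, np.sqrt(1 - h2), n)
        disease = (liab > norm.isf(K)).astype(float)
        # observed-scale variance fraction via OLS of status on the genetic value
        slope = np.cov(disease, g)[0, 1] / np.var(g)
        v_obs = slope**2 * np.var(g) / np.var(disease)
        rep = liability_variance(v_obs, K)
        assert rep.v_liab == pytest.approx(h2, rel=0.10)

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            liability_variance(0.1, 0.0)


class TestLRTest:
    def test_equal_likelihoods(self):
        stat, p = lr_test(-100.0, -100.0, 1)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        _, p = lr_test(-98.0795, -100.0, 1)  # stat = 3.841
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_misordered_models_rejected(self):
        with pytest.raises(ValueError, match="misordered"):
            lr_test(-105.0, -100.0, 1)
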