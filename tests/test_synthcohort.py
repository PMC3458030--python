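"""Generator tests: HWE sampling, additive phenotypes, disease model, depth."""

import numpy as np
import pandas as pd
import pytest

from cnphap import presets
from cnphap.synthcohort import (
    CovariateSpec,
    DepthSimConfig,
    Haplotype,
    HaplotypeModel,
    collapse_genotypes,
    diplotype_probabilities,
    draw_diplotypes,
    indel_marker_observations,
    intercept_for_prevalence,
    perturb_cn_calls,
    simulate_cohort,
    simulate_covariates,
    simulate_depth,
    simulate_disease,
    simulate_quantitative,
)
from scipy.special import expit, logit


def binom_se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestDiplotypeDraw:
    def test_degenerate_single_haplotype(self):
        m = HaplotypeModel(
            haplotypes=(Haplotype("T", 1), Haplotype("C", 1)), freqs=np.array([1.0, 0.0])
        )
        d = draw_diplotypes(m, 10, seed=0)
        assert np.all(d == 0)

    def test_gwas_frequency_recovered(self, gwas_model):
        """Sample frequency of the C/1 haplotype near its population value."""
        n = 10_000
        d = draw_diplotypes(gwas_model, n, seed=1)
        labels = [h.label for h in gwas_model.haplotypes]
        i = labels.index("C/1")
        p_hat = np.mean(d == i)  # over 2n haplotypes
        p_true = gwas_model.freqs[i]
        assert abs(p_hat - p_true) < 3 * binom_se(p_true, 2 * n)

    def test_hwe_heterozygote_fraction(self):
        """Two equifrequent haplotypes: heterozygote fraction 2pq = 0.5."""
        m = HaplotypeModel(
            haplotypes=(Haplotype("T", 1), Haplotype("C", 1)), freqs=np.array([0.5, 0.5])
        )
        n = 100_000
        d = draw_diplotypes(m, n, seed=2)
        het = np.mean(d[:, 0] != d[:, 1])
        assert abs(het - 0.5) < 3 * binom_se(0.5, n)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            HaplotypeModel(
                haplotypes=(Haplotype("T", 1), Haplotype("C", 1)),
                freqs=np.array([0.6, 0.5]),
            )

    def test_determinism(self, gwas_model):
        a = draw_diplotypes(gwas_model, 500, seed=42)
        b = draw_diplotypes(gwas_model, 500, seed=42)
        assert np.array_equal(a, b)

    def test_phase_ambiguous_fraction_matches_hwe(self, gwas_model):
        """(SNP het, total CN 2) individuals occur at their HWE-expected rate."""
        n = 50_000
        d = draw_diplotypes(gwas_model, n, seed=3)
        gt, cn = collapse_genotypes(d, gwas_model)
        frac = np.mean((gt == 1) & (cn == 2))
        # enumeration oracle over all unordered diplotypes
        pairs, probs = diplotype_probabilities(gwas_model.freqs)
        alt = np.array([h.snp_allele == "C" for h in gwas_model.haplotypes], dtype=int)
        hcn = np.array([h.hap_cn for h in gwas_model.haplotypes])
        is_class = (alt[pairs[:, 0]] + alt[pairs[:, 1]] == 1) & (
            hcn[pairs[:, 0]] + hcn[pairs[:, 1]] == 2
        )
        expected = probs[is_class].sum()
        assert abs(frac - expected) < 3 * binom_se(expected, n)

    def test_conservation_total_cn(self, gwas_model):
        d = draw_diplotypes(gwas_model, 1000, seed=4)
        _, cn = collapse_genotypes(d, gwas_model)
        hcn = np.array([h.hap_cn for h in gwas_model.haplotypes])
        assert np.array_equal(cn, hcn[d[:, 0]] + hcn[d[:, 1]])


class TestQuantitative:
    def test_null_genetics_exact_covariate_term(self, rng):
        m = HaplotypeModel(
            haplotypes=(Haplotype("T", 1), Haplotype("C", 1)),
            freqs=np.array([0.5, 0.5]),
            effects=np.array([0.0, 0.0]),
        )
        d = draw_diplotypes(m, 100, rng)
        cov = pd.DataFrame({"age": rng.normal(50, 5, 100)})
        y = simulate_quantitative(
            d, m, sigma_e=0.0, seed=rng, covariates=cov, covariate_effects={"age": 0.3}
        )
        assert np.allclose(y, 0.3 * cov["age"].to_numpy())

    def test_homozygote_contrast_is_twice_effect(self, gwas_model):
        """With no noise, del-hap homozygotes sit 2 x (-4.00) below ref homozygotes."""
        labels = [h.label for h in gwas_model.haplotypes]
        i_del, i_ref = labels.index("T/0"), labels.index("T/1")
        d = np.array([[i_del, i_del], [i_ref, i_ref]])
        y = simulate_quantitative(d, gwas_model, sigma_e=0.0, seed=0)
        assert y[0] - y[1] == pytest.approx(2 * -4.00)

    def test_genetic_variance_matches_hwe_enumeration(self, gwas_model):
        """Empirical genetic variance matches 2(sum p b^2 - (sum p b)^2) within 2%."""
        n = 200_000
        d = draw_diplotypes(gwas_model, n, seed=5)
        y = simulate_quantitative(d, gwas_model, sigma_e=0.0, seed=6)
        p, b = gwas_model.freqs, gwas_model.effects
        expected = 2 * (np.sum(p * b**2) - np.sum(p * b) ** 2)
        assert np.var(y) == pytest.approx(expected, rel=0.02)

    def test_covariate_length_mismatch(self, gwas_model):
        d = draw_diplotypes(gwas_model, 10, seed=0)
        cov = pd.DataFrame({"age": np.ones(5)})
        with pytest.raises(ValueError, match="covariate"):
            simulate_quantitative(d, gwas_model, 1.0, 0, covariates=cov)


class TestDisease:
    def test_null_prevalence(self):
        m = HaplotypeModel(
            haplotypes=(Haplotype("T", 1), Haplotype("C", 1)),
            freqs=np.array([0.5, 0.5]),
            log_or=np.array([0.0, 0.0]),
        )
        n = 100_000
        d = draw_diplotypes(m, n, seed=7)
        status, _, _ = simulate_disease(d, m, intercept=logit(0.1), case_n=10, control_n=10, seed=8)
        assert abs(status.mean() - 0.1) < 3 * binom_se(0.1, n)

    def test_deletion_haplotype_depleted_in_cases(self):
        """Protective deletion haplotype (OR 0.20) is rarer among cases."""
        model = presets.disease_model("copd")
        alpha = intercept_for_prevalence(model, 0.01)
        d = draw_diplotypes(model, 120_000, seed=9)
        _, cases, controls = simulate_disease(d, model, alpha, 900, 4000, seed=10)
        labels = [h.label for h in model.haplotypes]
        i = labels.index("T/0")
        f_case = np.mean(d[cases] == i)
        f_ctrl = np.mean(d[controls] == i)
        assert f_case < f_ctrl

    def test_case_haplotype_frequency_matches_enumeration(self):
        """Case-group haplotype frequency equals the brute-force expectation."""
        model = presets.disease_model("copd")
        alpha = intercept_for_prevalence(model, 0.01)
        n = 200_000
        d = draw_diplotypes(model, n, seed=11)
        status, _, _ = simulate_disease(d, model, alpha, 10, 10, seed=12)
        pairs, probs = diplotype_probabilities(model.freqs)
        p_case_d = expit(alpha + model.log_or[pairs[:, 0]] + model.log_or[pairs[:, 1]])
        labels = [h.label for h in model.haplotypes]
        i = labels.index("T/0")
        n_h = (pairs[:, 0] == i).astype(int) + (pairs[:, 1] == i).astype(int)
        expected = np.sum(probs * p_case_d * n_h) / (2 * np.sum(probs * p_case_d))
        case_idx = status == 1
        observed = np.mean(d[case_idx] == i)
        n_case_haps = 2 * case_idx.sum()
        assert abs(observed - expected) < 3 * binom_se(expected, n_case_haps)

    def test_unattainable_counts_error_names_prevalence(self, gwas_model):
        m = presets.disease_model("copd")
        d = draw_diplotypes(m, 100, seed=0)
        with pytest.raises(ValueError, match="prevalence"):
            simulate_disease(d, m, intercept=logit(0.01), case_n=90, control_n=90, seed=0)


class TestDepth:
    CFG = dict(start=0, end=3000, del_start=1000, del_end=2000, mean_coverage=10.0)

    def test_mean_depth_by_copy_number(self):
        cfg = DepthSimConfig(**self.CFG)
        cn = np.array([2, 0, 1, 4])
        dm = simulate_depth(cn, cfg, seed=13)
        inside = (dm.positions >= 1000) & (dm.positions < 2000)
        m = dm.depth[:, inside].mean(axis=1)
        se = np.sqrt(10.0 / inside.sum())
        assert abs(m[0] - 10.0) < 3 * se  # cn=2: full coverage
        assert m[1] == 0.0  # homozygous deletion
        assert abs(m[2] - 5.0) < 3 * se
        assert abs(m[3] - 20.0) < 3 * 2 * se

    def test_normalized_depth_outside_deletion_is_two(self):
        """Outside the deletion, normalised depth centres at 2 regardless of CN."""
        cfg = DepthSimConfig(**self.CFG)
        cn = np.repeat([0, 1, 2], 17)[:50]
        dm = simulate_depth(cn, cfg, seed=14)
        outside = dm.positions < 1000
        normed = 2.0 * dm.depth[:, outside] / dm.chrom_mean[:, None]
        per_sample = normed.mean(axis=1)
        se = 2.0 * np.sqrt(10.0 / outside.sum()) / 10.0
        assert np.all(np.abs(per_sample - 2.0) < 4 * se)

    def test_overdispersed_noise_variance(self):
        cfg = DepthSimConfig(**self.CFG, overdispersion=3.0)
        dm = simulate_depth(np.array([2] * 5), cfg, seed=15)
        outside = dm.positions < 1000
        v = dm.depth[:, outside].var()
        assert 2.0 * 10.0 < v < 4.5 * 10.0  # ~ od * mu

    def test_config_validation(self):
        with pytest.raises(ValueError, match="inside"):
            DepthSimConfig(start=0, end=100, del_start=50, del_end=200, mean_coverage=5)
        with pytest.raises(ValueError, match="empty region"):
            DepthSimConfig(start=100, end=100, del_start=40, del_end=50, mean_coverage=5)

    def test_determinism(self):
        cfg = DepthSimConfig(**self.CFG)
        a = simulate_depth(np.array([0, 1, 2]), cfg, seed=16)
        b = simulate_depth(np.array([0, 1, 2]), cfg, seed=16)
        assert np.array_equal(a.depth, b.depth)
        assert np.array_equal(a.chrom_mean, b.chrom_mean)


class TestMisc:
    def test_cohort_reproducible(self, gwas_model):
        a = simulate_cohort(gwas_model, 200, sigma_e=16.9, seed=5, covariate_spec=CovariateSpec())
        b = simulate_cohort(gwas_model, 200, sigma_e=16.9, seed=5, covariate_spec=CovariateSpec())
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_covariate_distributions(self, rng):
        cov = simulate_covariates(CovariateSpec(), 20_000, rng)
        assert cov["age"].min() >= 20.0
        assert abs(cov["sex"].mean() - 0.5) < 0.02
        assert np.allclose(cov["age_sq"], cov["age"] ** 2)

    def test_cn_call_noise_bounded(self, rng):
        cn = np.array([0, 1, 2, 3, 4] * 200)
        noisy = perturb_cn_calls(cn, accuracy=0.5, seed=rng)
        assert noisy.min() >= 0 and noisy.max() <= 4
        assert np.mean(noisy != cn) < 0.6

    def test_indel_marker_consistency(self, gwas_model):
        """In-deletion marker call and region CN always match the true diplotype."""
        c = simulate_cohort(gwas_model, 2000, seed=17)
        gt, region_cn = indel_marker_observations(c)
        hcn = np.array([h.hap_cn for h in gwas_model.haplotypes])
        surv = (hcn[c.diplotypes[:, 0]] > 0).astype(int) + (hcn[c.diplotypes[:, 1]] > 0).astype(int)
        assert np.array_equal(region_cn, surv)
        assert np.all((gt >= 0) & (gt <= 2))
        assert np.all(gt[region_cn == 0] == 0)
        assert np.all(gt[region_cn == 1] % 2 == 0)  # hemizygous calls are 0 or 2
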