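"""Parameter-recovery studies on cohorts simulated from the published models.

Each function simulates cohorts whose generative truth is a published
haplotype table — the GWAS-set CPD frequencies/effects for the quantitative
trait, the disease control-column frequencies and odds ratios for the
case-control traits — runs the EM haplotype-specific regression on the
collapsed (phase-ambiguous) genotypes, and averages the estimates across
seeds.  Effects and frequencies are averaged arithmetically; odds ratios are
averaged on the log scale (geometric mean) to avoid the Jensen bias of
averaging exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import presets
from .haploreg import anova_explained, fit_haplo_linear, fit_haplo_logistic
from .synthcohort import (
    collapse_genotypes,
    draw_diplotypes,
    intercept_for_prevalence,
    simulate_disease,
    simulate_quantitative,
)

__all__ = ["CPDRecovery", "DiseaseRecovery", "cpd_recovery", "disease_recovery"]

GWAS_N = 11_696
DISEASE_PREVALENCE = 0.01
DISEASE_POPULATION = 150_000


def _child_seeds(seed: int, k: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=k)


@dataclass
class CPDRecovery:
    """Averaged EM estimates from GWAS-scale quantitative cohorts."""

    effect_del: float  # T/0-copy effect (cigarettes/day vs reference)
    effect_mut: float  # C/1-copy effect
    freq_del_pct: float
    freq_ref_pct: float
    explained_variance_pct: float
    n: int
    n_seeds: int
    per_seed: dict


def cpd_recovery(seed: int = 1, n_seeds: int = 10, n: int = GWAS_N) -> CPDRecovery:
    """Simulate the GWAS-set CPD cohort and recover haplotype parameters by EM.

    Per seed: draw n diplotypes under HWE from the GWAS-set six-haplotype
    frequencies, phenotype = summed haplotype effects + Normal(0, 16.9^2),
    collapse to (SNP genotype, total CN), fit the six-haplotype EM linear
    regression with T/1 as reference, and compute the ANOVA explained
    variance on expected dosages.
    """
    model = presets.cpd_gwas_model()
    eff_del, eff_mut, f_del, f_ref, ev = [], [], [], [], []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(int(s))
        dipl = draw_diplotypes(model, n, rng)
        y = simulate_quantitative(dipl, model, presets.CPD_RESIDUAL_SD, rng)
        snp_gt, total_cn = collapse_genotypes(dipl, model)
        fit = fit_haplo_linear(
            y, snp_gt, total_cn, reference="T/1", compute_se=False
        )
        labels = [h.label for h in fit.universe]
        eff_del.append(float(fit.effects[labels.index("T/0")]))
        eff_mut.append(float(fit.effects[labels.index("C/1")]))
        f_del.append(100.0 * float(fit.freqs[labels.index("T/0")]))
        f_ref.append(100.0 * float(fit.freqs[labels.index("T/1")]))
        ev.append(100.0 * anova_explained(fit, y).explained_fraction)
    return CPDRecovery(
        effect_del=float(np.mean(eff_del)),
        effect_mut=float(np.mean(eff_mut)),
        freq_del_pct=float(np.mean(f_del)),
        freq_ref_pct=float(np.mean(f_ref)),
        explained_variance_pct=float(np.mean(ev)),
        n=n,
        n_seeds=n_seeds,
        per_seed={
            "effect_del": eff_del,
            "effect_mut": eff_mut,
            "freq_del_pct": f_del,
            "freq_ref_pct": f_ref,
            "explained_variance_pct": ev,
        },
    )


@dataclass
class DiseaseRecovery:
    """Geometric-mean odds ratios recovered from case-control simulations."""

    or_del: float  # T/0-copy odds ratio vs reference
    or_mut: float  # C/1-copy odds ratio
    case_n: int
    control_n: int
    n_seeds: int
    per_seed: dict


def disease_recovery(
    disease: str,
    seed: int = 1,
    n_seeds: int = 15,
    population: int = DISEASE_POPULATION,
    prevalence: float = DISEASE_PREVALENCE,
) -> DiseaseRecovery:
    """Simulate a case-control study for one disease and recover the ORs by EM.

    Per seed: draw a large population under HWE from the disease's
    control-column haplotype frequencies, assign status by the logistic model
    with the published per-haplotype log-ORs and an intercept solved for the
    target prevalence, sample the study's case/control counts, and fit the
    EM haplotype logistic regression on the collapsed genotypes.
    """
    design = presets.DISEASE_DESIGNS[disease]
    model = presets.disease_model(disease)
    alpha = intercept_for_prevalence(model, prevalence)
    case_n, control_n = design["case_n"], design["control_n"]
    lor_del, lor_mut = [], []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(int(s))
        dipl = draw_diplotypes(model, population, rng)
        _, cases, controls = simulate_disease(
            dipl, model, alpha, case_n, control_n, rng
        )
        keep = np.concatenate([cases, controls])
        status = np.concatenate([np.ones(case_n), np.zeros(control_n)]).astype(int)
        snp_gt, total_cn = collapse_genotypes(dipl[keep], model)
        # rare haplotypes (~0.2-0.8%) occasionally separate in a single draw;
        # the common-haplotype log-ORs of interest are unaffected
        fit = fit_haplo_logistic(
            status, snp_gt, total_cn, reference="T/1", compute_se=False,
            on_separation="warn",
        )
        labels = [h.label for h in fit.universe]
        lor_del.append(fit.effects[labels.index("T/0")])
        lor_mut.append(fit.effects[labels.index("C/1")])
    return DiseaseRecovery(
        or_del=float(np.exp(np.mean(lor_del))),
        or_mut=float(np.exp(np.mean(lor_mut))),
        case_n=case_n,
        control_n=control_n,
        n_seeds=n_seeds,
        per_seed={"log_or_del": lor_del, "log_or_mut": lor_mut},
    )
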