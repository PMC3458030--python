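"""Published CYP2A6-locus haplotype models used as generative truth.

The locus carries six haplotypes, each a combination of the tag-SNP allele
(T ancestral / C mutant) and the haplotypic copy number of the CYP2A6 gene
(0 = deletion, 1 = normal, 2 = duplication).  The dictionaries below hold the
haplotype frequencies (percent), relative CPD effects (cigarettes/day versus
the T/1 reference haplotype) and disease odds ratios estimated in a Japanese
GWAS cohort; they serve as inputs when simulating cohorts with realistic
structure.  Frequency columns are printed to two decimals and are renormalised
to sum to one when a model is built.
"""

from __future__ import annotations

from .synthcohort import HaplotypeModel

__all__ = [
    "CPD_RESIDUAL_SD",
    "cpd_gwas_model",
    "cpd_replication_model",
    "disease_model",
    "DISEASE_DESIGNS",
]

REFERENCE_HAP = "T/1"

# GWAS set (n = 11,696): haplotype frequency (%) and relative CPD effect
CPD_GWAS_FREQ_PCT = {
    "T/1": 41.41,
    "T/0": 19.22,
    "C/1": 38.14,
    "C/0": 0.76,
    "C/2": 0.23,
    "T/2": 0.28,
}
CPD_GWAS_EFFECT = {
    "T/1": 0.0,
    "T/0": -4.00,
    "C/1": -2.69,
    "C/0": -5.05,
    "C/2": -3.07,
    "T/2": -0.29,
}

# Replication set (n = 5,462)
CPD_REPL_FREQ_PCT = {
    "T/1": 41.8,
    "T/0": 18.6,
    "C/1": 38.4,
    "C/0": 0.63,
    "C/2": 0.24,
    "T/2": 0.31,
}
CPD_REPL_EFFECT = {
    "T/1": 0.0,
    "T/0": -4.30,
    "C/1": -2.63,
    "C/0": -3.84,
    "C/2": -2.62,
    "T/2": -0.414,
}

# Residual SD of CPD about the haplotype effects.  Derived: with the GWAS
# frequencies/effects above, sigma_e = 16.9 makes the haplotype component
# explain 1.83% of phenotypic variance, the explained-variance figure the
# six haplotypes account for in that cohort.
CPD_RESIDUAL_SD = 16.9

# Case-control designs: control-column haplotype frequencies (%) and odds
# ratios versus the reference haplotype, with study case/control counts.
DISEASE_DESIGNS: dict[str, dict] = {
    "copd": {
        "control_freq_pct": {
            "T/1": 39.61,
            "T/0": 19.76,
            "C/1": 39.45,
            "C/0": 0.64,
            "C/2": 0.23,
            "T/2": 0.31,
        },
        "odds_ratios": {
            "T/1": 1.0,
            "T/0": 0.20,
            "C/1": 0.38,
            "C/0": 0.40,
            "C/2": 3.28,
            "T/2": 0.53,
        },
        "case_n": 982,
        "control_n": 4480,
    },
    "lung_cancer": {
        "control_freq_pct": {
            "T/1": 41.15,
            "T/0": 19.47,
            "C/1": 38.12,
            "C/0": 0.76,
            "C/2": 0.25,
            "T/2": 0.27,
        },
        "odds_ratios": {
            "T/1": 1.0,
            "T/0": 0.33,
            "C/1": 0.55,
            "C/0": 0.29,
            "C/2": 1.25,
            "T/2": 0.24,
        },
        "case_n": 997,
        "control_n": 6491,
    },
    "aso": {
        "control_freq_pct": {
            "T/1": 41.11,
            "T/0": 19.41,
            "C/1": 38.19,
            "C/0": 0.77,
            "C/2": 0.23,
            "T/2": 0.29,
        },
        "odds_ratios": {
            "T/1": 1.0,
            "T/0": 0.53,
            "C/1": 0.72,
            "C/0": 0.99,
            "C/2": 0.77,
            "T/2": 1.24,
        },
        "case_n": 499,
        "control_n": 10975,
    },
}


def cpd_gwas_model() -> HaplotypeModel:
    """Six-haplotype model with the GWAS-set frequencies and CPD effects."""
    return HaplotypeModel.from_percent(
        CPD_GWAS_FREQ_PCT, effects=CPD_GWAS_EFFECT, reference=REFERENCE_HAP
    )


def cpd_replication_model() -> HaplotypeModel:
    """Six-haplotype model with the replication-set frequencies and effects."""
    return HaplotypeModel.from_percent(
        CPD_REPL_FREQ_PCT, effects=CPD_REPL_EFFECT, reference=REFERENCE_HAP
    )


def disease_model(disease: str) -> HaplotypeModel:
    """Case-control generative model for one disease (copd, lung_cancer, aso).

    Population haplotype frequencies are taken from the control column — at
    ~1% prevalence controls are representative of the population — and the
    per-haplotype log-ORs are the logs of the published odds ratios.
    """
    d = DISEASE_DESIGNS[disease]
    return HaplotypeModel.from_percent(
        d["control_freq_pct"], odds_ratios=d["odds_ratios"], reference=REFERENCE_HAP
    )
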