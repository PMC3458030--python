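"""Seeded synthetic cohorts with the statistical structure of a CNP/SNP locus.

The locus model is one biallelic SNP combined with a haplotypic copy number in
{0, 1, 2}: six possible haplotypes.  Individuals carry an unordered pair of
haplotypes (a diplotype) drawn under Hardy-Weinberg random mating.  What an
assay observes is the collapsed genotype — the diploid SNP genotype (count of
alternate alleles) and the total copy number (sum of the two haplotypic copy
numbers) — which is phase-ambiguous for SNP heterozygotes with total copy
number 2.  Quantitative phenotypes are additive in the per-haplotype effects;
disease status follows a logistic model in per-haplotype log odds ratios.

Read depth across a genomic window containing a common deletion is simulated
as count noise around ``coverage * cn/2`` inside the deleted segment and
``coverage`` outside, together with a per-sample chromosome-wide mean coverage
for normalisation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "Haplotype",
    "HaplotypeModel",
    "CovariateSpec",
    "SimulatedCohort",
    "DepthSimConfig",
    "DepthMatrix",
    "haplotype_universe",
    "diplotype_pairs",
    "diplotype_probabilities",
    "draw_diplotypes",
    "collapse_genotypes",
    "simulate_covariates",
    "simulate_quantitative",
    "intercept_for_prevalence",
    "simulate_disease",
    "simulate_cohort",
    "perturb_cn_calls",
    "simulate_depth",
    "indel_marker_observations",
]


@dataclass(frozen=True, order=True)
class Haplotype:
    """One haplotype: a SNP allele plus the copy number it carries (0, 1 or 2)."""

    snp_allele: str
    hap_cn: int

    def __post_init__(self) -> None:
        if self.hap_cn not in (0, 1, 2):
            raise ValueError(f"hap_cn must be in {{0,1,2}}, got {self.hap_cn}")

    @property
    def label(self) -> str:
        return f"{self.snp_allele}/{self.hap_cn}"

    @classmethod
    def from_label(cls, label: str) -> "Haplotype":
        allele, cn = label.split("/")
        return cls(allele, int(cn))


def haplotype_universe(ref_allele: str = "T", alt_allele: str = "C") -> tuple[Haplotype, ...]:
    """The six haplotypes of one biallelic SNP x haplotypic copy number {0,1,2}."""
    return tuple(
        Haplotype(a, c) for a in (ref_allele, alt_allele) for c in (0, 1, 2)
    )


@dataclass
class HaplotypeModel:
    """Population haplotype frequencies plus phenotype/disease effects.

    ``effects`` are additive quantitative-trait effects per haplotype copy,
    with the reference haplotype fixed at zero; ``log_or`` likewise holds
    per-haplotype log odds ratios for a binary disease.
    """

    haplotypes: tuple[Haplotype, ...]
    freqs: np.ndarray
    effects: np.ndarray | None = None
    log_or: np.ndarray | None = None
    reference: Haplotype | None = None
    ref_allele: str = "T"
    alt_allele: str = "C"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.freqs) != len(self.haplotypes):
            raise ValueError("freqs and haplotypes length mismatch")
        if np.any(self.freqs < 0):
            raise ValueError("haplotype frequencies must be nonnegative")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"haplotype frequencies must sum to 1 (got {self.freqs.sum():.15g}); "
                "pass normalised frequencies or use from_percent(normalise=True)"
            )
        if self.effects is not None:
            self.effects = np.asarray(self.effects, dtype=float)
        if self.log_or is not None:
            self.log_or = np.asarray(self.log_or, dtype=float)
        if self.reference is not None:
            r = self.index_of(self.reference)
            if self.effects is not None and self.effects[r] != 0.0:
                raise ValueError("reference haplotype must have effect 0")
            if self.log_or is not None and self.log_or[r] != 0.0:
                raise ValueError("reference haplotype must have log-OR 0")

    def index_of(self, hap: Haplotype) -> int:
        return self.haplotypes.index(hap)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @classmethod
    def from_percent(
        cls,
        freq_pct: dict[str, float],
        effects: dict[str, float] | None = None,
        odds_ratios: dict[str, float] | None = None,
        reference: str = "T/1",
        normalise: bool = True,
        ref_allele: str = "T",
        alt_allele: str = "C",
    ) -> "HaplotypeModel":
        """Build a model from label->percent frequencies and per-haplotype effects.

        Published frequency columns are rounded to 2 decimals and may not sum to
        exactly 100%; ``normalise=True`` rescales them to a proper distribution.
        """
        haps = tuple(Haplotype.from_label(lbl) for lbl in freq_pct)
        f = np.array([freq_pct[h.label] for h in haps], dtype=float) / 100.0
        if normalise:
            f = f / f.sum()
        eff = None
        if effects is not None:
            eff = np.array([effects.get(h.label, 0.0) for h in haps])
        lor = None
        if odds_ratios is not None:
            lor = np.array([np.log(odds_ratios.get(h.label, 1.0)) for h in haps])
        return cls(
            haplotypes=haps,
            freqs=f,
            effects=eff,
            log_or=lor,
            reference=Haplotype.from_label(reference),
            ref_allele=ref_allele,
            alt_allele=alt_allele,
        )


# ---------------------------------------------------------------------------
# diplotype machinery


def diplotype_pairs(n_haps: int) -> np.ndarray:
    """All unordered haplotype-index pairs (i <= j), shape (n_pairs, 2)."""
    return np.array([(i, j) for i in range(n_haps) for j in range(i, n_haps)])


def diplotype_probabilities(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HWE probability of each unordered diplotype: p_i p_j, doubled off-diagonal."""
    pairs = diplotype_pairs(len(freqs))
    p = freqs[pairs[:, 0]] * freqs[pairs[:, 1]]
    p = np.where(pairs[:, 0] != pairs[:, 1], 2.0 * p, p)
    return pairs, p


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_diplotypes(model: HaplotypeModel, n: int, seed) -> np.ndarray:
    """Draw n diplotypes (unordered haplotype-index pairs) under HWE.

    Each individual's two haplotypes are i.i.d. draws from the frequency
    vector; the returned array has shape (n, 2) with row-wise sorted indices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    idx = rng.choice(model.n_haplotypes, size=(n, 2), p=model.freqs)
    idx.sort(axis=1)
    return idx


def collapse_genotypes(
    diplotypes: np.ndarray, model: HaplotypeModel
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse true diplotypes to the observable (SNP genotype, total CN).

    SNP genotype is the alternate-allele count 0/1/2; total copy number is the
    sum of the two haplotypic copy numbers (0..4).  Phase is lost exactly where
    it is lost in real data.
    """
    alt = np.array([h.snp_allele == model.alt_allele for h in model.haplotypes], dtype=int)
    cn = np.array([h.hap_cn for h in model.haplotypes])
    snp_gt = alt[diplotypes[:, 0]] + alt[diplotypes[:, 1]]
    total_cn = cn[diplotypes[:, 0]] + cn[diplotypes[:, 1]]
    return snp_gt, total_cn


# ---------------------------------------------------------------------------
# covariates


@dataclass
class CovariateSpec:
    """Distributions and effect sizes for the standard covariate set.

    Defaults: sex ~ Bernoulli(0.5), age ~ Normal(55, 10) truncated at 20 (with
    age^2 derived), smoking cessation ~ Bernoulli(0.4), two ancestry PCs
    ~ Normal(0, 1).  All effects default to zero.
    """

    sex_p: float = 0.5
    age_mean: float = 55.0
    age_sd: float = 10.0
    age_min: float = 20.0
    cessation_p: float = 0.4
    effects: dict[str, float] = field(default_factory=dict)

    columns = ("sex", "age", "age_sq", "cessation", "pc1", "pc2")


def simulate_covariates(spec: CovariateSpec, n: int, seed) -> pd.DataFrame:
    rng = _as_rng(seed)
    sex = rng.binomial(1, spec.sex_p, n)
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    while np.any(age < spec.age_min):  # truncate by redrawing the tail
        bad = age < spec.age_min
        age[bad] = rng.normal(spec.age_mean, spec.age_sd, bad.sum())
    cess = rng.binomial(1, spec.cessation_p, n)
    pc1 = rng.normal(0.0, 1.0, n)
    pc2 = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(
        {"sex": sex, "age": age, "age_sq": age**2, "cessation": cess, "pc1": pc1, "pc2": pc2}
    )


def _covariate_term(covariates: pd.DataFrame | None, effects: dict[str, float]) -> np.ndarray | float:
    if covariates is None or not effects:
        return 0.0
    term = np.zeros(len(covariates))
    for col, eff in effects.items():
        term += eff * covariates[col].to_numpy(dtype=float)
    return term


# ---------------------------------------------------------------------------
# phenotypes


def simulate_quantitative(
    diplotypes: np.ndarray,
    model: HaplotypeModel,
    sigma_e: float,
    seed,
    covariates: pd.DataFrame | None = None,
    covariate_effects: dict[str, float] | None = None,
    round_to_int: bool = False,
) -> np.ndarray:
    """Quantitative phenotype: covariate term + sum of haplotype effects + noise.

    y_i = x_i'gamma + beta_{h1(i)} + beta_{h2(i)} + eps_i, eps ~ Normal(0, sigma_e^2).
    ``round_to_int`` optionally rounds and truncates at zero (off by default:
    the trait is analysed as a continuous linear-model response).
    """
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    if model.effects is None:
        raise ValueError("model has no quantitative effects")
    if covariates is not None and len(covariates) != len(diplotypes):
        raise ValueError("covariate row count does not match number of individuals")
    rng = _as_rng(seed)
    gen = model.effects[diplotypes[:, 0]] + model.effects[diplotypes[:, 1]]
    y = gen + _covariate_term(covariates, covariate_effects or {})
    y = y + rng.normal(0.0, sigma_e, len(diplotypes))
    if round_to_int:
        y = np.maximum(np.round(y), 0.0)
    return y


def intercept_for_prevalence(model: HaplotypeModel, prevalence: float) -> float:
    """Logistic intercept giving the requested marginal disease prevalence.

    Solves sum_d P(d) * expit(alpha + eta_d) = K by enumerating all diplotypes
    under HWE, where eta_d is the diplotype's summed log-OR.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    if model.log_or is None:
        raise ValueError("model has no disease log-ORs")
    pairs, pd_ = diplotype_probabilities(model.freqs)
    eta = model.log_or[pairs[:, 0]] + model.log_or[pairs[:, 1]]

    def f(alpha: float) -> float:
        return float(np.sum(pd_ * expit(alpha + eta))) - prevalence

    return brentq(f, -40.0, 20.0)


def simulate_disease(
    diplotypes: np.ndarray,
    model: HaplotypeModel,
    intercept: float,
    case_n: int,
    control_n: int,
    seed,
    covariates: pd.DataFrame | None = None,
    covariate_effects: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary status under the per-haplotype log-OR logistic model.

    Returns (status over the whole population, case indices, control indices)
    with exactly ``case_n`` cases and ``control_n`` controls sampled without
    replacement.  Raises with the achieved prevalence if counts are
    unattainable.
    """
    if model.log_or is None:
        raise ValueError("model has no disease log-ORs")
    rng = _as_rng(seed)
    eta = (
        intercept
        + model.log_or[diplotypes[:, 0]]
        + model.log_or[diplotypes[:, 1]]
        + _covariate_term(covariates, covariate_effects or {})
    )
    status = rng.random(len(diplotypes)) < expit(eta)
    n_case, n_ctrl = int(status.sum()), int((~status).sum())
    if n_case < case_n or n_ctrl < control_n:
        raise ValueError(
            f"population of {len(status)} yielded {n_case} cases / {n_ctrl} controls "
            f"(prevalence {n_case / len(status):.4f}); cannot sample "
            f"{case_n} cases and {control_n} controls"
        )
    cases = rng.choice(np.flatnonzero(status), size=case_n, replace=False)
    controls = rng.choice(np.flatnonzero(~status), size=control_n, replace=False)
    return status.astype(int), np.sort(cases), np.sort(controls)


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class SimulatedCohort:
    """A simulated cohort: truth, collapsed observables, phenotype, covariates."""

    model: HaplotypeModel
    diplotypes: np.ndarray  # (n, 2) haplotype indices, row-sorted
    snp_gt: np.ndarray
    total_cn: np.ndarray
    phenotype: np.ndarray | None
    status: np.ndarray | None
    covariates: pd.DataFrame | None
    sigma_e: float | None
    seed: int | None

    def __post_init__(self) -> None:
        cn = np.array([h.hap_cn for h in self.model.haplotypes])
        if not np.array_equal(
            self.total_cn, cn[self.diplotypes[:, 0]] + cn[self.diplotypes[:, 1]]
        ):
            raise ValueError("total_cn inconsistent with diplotypes")

    @property
    def n(self) -> int:
        return len(self.diplotypes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": [f"S{i:06d}" for i in range(self.n)],
                "hap1": [self.model.haplotypes[i].label for i in self.diplotypes[:, 0]],
                "hap2": [self.model.haplotypes[i].label for i in self.diplotypes[:, 1]],
                "snp_gt": self.snp_gt,
                "total_cn": self.total_cn,
            }
        )
        if self.phenotype is not None:
            df["phenotype"] = self.phenotype
        if self.status is not None:
            df["status"] = self.status
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df

    def subset(self, idx: np.ndarray) -> "SimulatedCohort":
        return replace(
            self,
            diplotypes=self.diplotypes[idx],
            snp_gt=self.snp_gt[idx],
            total_cn=self.total_cn[idx],
            phenotype=None if self.phenotype is None else self.phenotype[idx],
            status=None if self.status is None else self.status[idx],
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[idx].reset_index(drop=True),
        )


def simulate_cohort(
    model: HaplotypeModel,
    n: int,
    sigma_e: float | None = None,
    seed: int = 0,
    covariate_spec: CovariateSpec | None = None,
) -> SimulatedCohort:
    """Draw a full quantitative-trait cohort (diplotypes, phenotype, covariates)."""
    rng = np.random.default_rng(seed)
    dipl = draw_diplotypes(model, n, rng)
    snp_gt, total_cn = collapse_genotypes(dipl, model)
    cov = None
    if covariate_spec is not None:
        cov = simulate_covariates(covariate_spec, n, rng)
    pheno = None
    if sigma_e is not None:
        pheno = simulate_quantitative(
            dipl,
            model,
            sigma_e,
            rng,
            covariates=cov,
            covariate_effects=covariate_spec.effects if covariate_spec else None,
        )
    return SimulatedCohort(
        model=model,
        diplotypes=dipl,
        snp_gt=snp_gt,
        total_cn=total_cn,
        phenotype=pheno,
        status=None,
        covariates=cov,
        sigma_e=sigma_e,
        seed=seed,
    )


def perturb_cn_calls(total_cn: np.ndarray, accuracy: float, seed) -> np.ndarray:
    """Emulate genotype-call error: with prob 1-accuracy shift the call by +-1.

    Bounded to [0, 4].  Models the small residual discordance of mixture-model
    MAP copy-number calls against wet-lab assays (>99% concordance regime).
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must be in (0,1]")
    rng = _as_rng(seed)
    out = np.asarray(total_cn).copy()
    flip = rng.random(len(out)) > accuracy
    step = rng.choice([-1, 1], size=len(out))
    out[flip] = np.clip(out[flip] + step[flip], 0, 4)
    return out


# ---------------------------------------------------------------------------
# depth simulation


@dataclass
class DepthSimConfig:
    """Window, deletion interval and noise model for read-depth simulation.

    Coordinates are 0-based half-open.  ``overdispersion`` is the
    variance/mean ratio of the per-base count noise (1.0 = Poisson).
    ``background_bases`` sets how many off-window diploid bases inform each
    sample's chromosome-mean coverage estimate.
    """

    chrom: str = "chr19"
    start: int = 41_344_000
    end: int = 41_356_000
    del_start: int = 41_347_000
    del_end: int = 41_350_000
    mean_coverage: float = 6.0
    overdispersion: float = 1.0
    background_bases: int = 2_000_000

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty region: end must exceed start")
        if not (self.start < self.del_start < self.del_end < self.end):
            raise ValueError("deletion interval must lie strictly inside the region")
        if self.mean_coverage <= 0:
            raise ValueError("mean coverage must be > 0")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1 (1 = Poisson)")


@dataclass
class DepthMatrix:
    """Per-individual per-base raw depth over a window, plus chromosome means."""

    positions: np.ndarray  # 0-based base coordinates, length m
    depth: np.ndarray  # (n, m) raw counts
    chrom_mean: np.ndarray  # (n,) chromosome-wide mean coverage per sample
    config: DepthSimConfig


def _count_noise(rng: np.random.Generator, mu: np.ndarray, overdispersion: float) -> np.ndarray:
    if overdispersion == 1.0:
        return rng.poisson(mu)
    # gamma-Poisson mixture: lambda ~ Gamma(shape=mu/(od-1), mean=mu) gives
    # counts with mean mu and variance od*mu
    shape = np.where(mu > 0, mu / (overdispersion - 1.0), 1.0)
    lam = rng.gamma(shape, (overdispersion - 1.0) * np.ones_like(mu))
    return rng.poisson(np.where(mu > 0, lam, 0.0))


def simulate_depth(total_cn: np.ndarray, cfg: DepthSimConfig, seed) -> DepthMatrix:
    """Raw read depth: expectation coverage*cn/2 inside the deletion, coverage outside.

    The per-sample chromosome mean is simulated from ``background_bases``
    diploid bases, so that normalising by it centres the depth at 2 for
    diploid samples, mirroring whole-chromosome mean normalisation (a common
    ~30 kb deletion is a negligible share of a chromosome's length).
    """
    total_cn = np.asarray(total_cn)
    rng = _as_rng(seed)
    positions = np.arange(cfg.start, cfg.end)
    in_del = (positions >= cfg.del_start) & (positions < cfg.del_end)
    mult = np.where(in_del[None, :], total_cn[:, None] / 2.0, 1.0)
    mu = cfg.mean_coverage * mult
    depth = _count_noise(rng, mu, cfg.overdispersion).astype(float)
    bg = rng.poisson(cfg.mean_coverage * cfg.background_bases, size=len(total_cn))
    chrom_mean = bg / cfg.background_bases
    return DepthMatrix(positions=positions, depth=depth, chrom_mean=chrom_mean, config=cfg)


# ---------------------------------------------------------------------------
# in-deletion marker observations (input to the tri-allelic recoding)


def indel_marker_observations(cohort: SimulatedCohort) -> tuple[np.ndarray, np.ndarray]:
    """Observed genotype of a marker lying inside the deleted segment.

    A haplotype carries the deletion iff its haplotypic copy number is 0, so
    the marker is observed on ``region_cn = #{haplotypes with cn > 0}`` copies
    (0, 1 or 2).  The SNP call is diploid-style (0/1/2 alternate-allele
    count): a hemizygous sample's single allele is reported as the matching
    homozygous call, as a diploid caller would.  Returns (call, region_cn).
    """
    cn = np.array([h.hap_cn for h in cohort.model.haplotypes])
    alt = np.array(
        [h.snp_allele == cohort.model.alt_allele for h in cohort.model.haplotypes], dtype=int
    )
    h1, h2 = cohort.diplotypes[:, 0], cohort.diplotypes[:, 1]
    present1, present2 = cn[h1] > 0, cn[h2] > 0
    region_cn = present1.astype(int) + present2.astype(int)
    n_alt = alt[h1] * present1 + alt[h2] * present2
    marker_gt = np.where(region_cn == 1, 2 * n_alt, n_alt)
    return marker_gt, region_cn
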