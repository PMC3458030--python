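"""Haplotype-specific regression over phase-ambiguous SNP x copy-number genotypes.

An individual's observable genotype — the diploid SNP genotype plus the total
copy number — is compatible with one or more diplotypes (unordered pairs of
the six SNP-allele x haplotypic-copy-number haplotypes).  Treating the true
diplotype as the latent variable, the model is

    y_i | d  ~  Normal(mu + sum_h beta_h n_h(d) + x_i' gamma, sigma^2)   (linear)
    s_i | d  ~  Bernoulli(expit(mu + sum_h theta_h n_h(d) + x_i' gamma)) (logistic)
    P(d | p) =  HWE prior p_h1 p_h2, doubled for heterozygous pairs,

with the reference haplotype's effect fixed at zero.  Frequencies p,
effects beta (or log-ORs theta), covariate coefficients and sigma^2 are
jointly estimated by EM on the observed-data likelihood
sum_d P(d|p) f(y|d); standard errors come from the numerically
differentiated observed-data log-likelihood.  Downstream summaries: ANOVA
explained variance on posterior-expected haplotype dosages, the
liability-threshold transformation of observed-scale variance, and the
likelihood-ratio test against the no-haplotype-effect null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import norm

from .synthcohort import Haplotype, HaplotypeModel, haplotype_universe

__all__ = [
    "DiplotypeSet",
    "HaploLinearFit",
    "HaploLogisticFit",
    "VarianceReport",
    "LiabilityReport",
    "enumerate_diplotypes",
    "fit_haplo_linear",
    "fit_haplo_logistic",
    "haplotype_frequencies_em",
    "anova_explained",
    "liability_variance",
    "lr_test",
]

_LOG2PI = np.log(2.0 * np.pi)


class SeparationError(RuntimeError):
    pass


@dataclass
class DiplotypeSet:
    """Compatible diplotypes for one observed (SNP genotype, total CN)."""

    pairs: np.ndarray  # (k, 2) haplotype indices into the universe
    het: np.ndarray  # pair has two distinct haplotypes (prior doubled)
    inconsistent: bool = False

    def prior_weights(self, freqs: np.ndarray) -> np.ndarray:
        w = freqs[self.pairs[:, 0]] * freqs[self.pairs[:, 1]]
        w = np.where(self.het, 2.0 * w, w)
        tot = w.sum()
        return w / tot if tot > 0 else w


def enumerate_diplotypes(
    snp_gt: int,
    total_cn: int,
    universe: tuple[Haplotype, ...] | None = None,
    alt_allele: str = "C",
) -> DiplotypeSet:
    """All unordered haplotype pairs matching the observed genotype.

    A pair matches when its alternate-allele count equals ``snp_gt`` and its
    haplotypic copy numbers sum to ``total_cn``.  An empty set is returned
    flagged inconsistent (never silently).
    """
    if universe is None:
        universe = haplotype_universe(alt_allele=alt_allele)
    if not 0 <= total_cn <= 4:
        raise ValueError("total copy number must be in 0..4")
    if snp_gt not in (0, 1, 2):
        raise ValueError("SNP genotype must be 0, 1 or 2")
    alt = np.array([h.snp_allele == alt_allele for h in universe], dtype=int)
    cn = np.array([h.hap_cn for h in universe])
    pairs, het = [], []
    H = len(universe)
    for i in range(H):
        for j in range(i, H):
            if alt[i] + alt[j] == snp_gt and cn[i] + cn[j] == total_cn:
                pairs.append((i, j))
                het.append(i != j)
    if not pairs:
        return DiplotypeSet(
            pairs=np.empty((0, 2), dtype=int), het=np.empty(0, dtype=bool), inconsistent=True
        )
    return DiplotypeSet(pairs=np.array(pairs), het=np.array(het))


# ---------------------------------------------------------------------------
# diplotype expansion shared by the linear and logistic fits


class _Expansion:
    """Row-expanded compatible diplotypes for a cohort, built once per fit."""

    def __init__(
        self,
        snp_gt: np.ndarray,
        total_cn: np.ndarray,
        universe: tuple[Haplotype, ...],
        alt_allele: str,
    ):
        self.universe = universe
        n = len(snp_gt)
        cache: dict[tuple[int, int], DiplotypeSet] = {}
        rows_ind, rows_h1, rows_h2, rows_het = [], [], [], []
        bad = []
        for i in range(n):
            key = (int(snp_gt[i]), int(total_cn[i]))
            ds = cache.get(key)
            if ds is None:
                ds = enumerate_diplotypes(key[0], key[1], universe, alt_allele)
                cache[key] = ds
            if ds.inconsistent:
                bad.append(i)
                continue
            k = len(ds.pairs)
            rows_ind.extend([i] * k)
            rows_h1.extend(ds.pairs[:, 0])
            rows_h2.extend(ds.pairs[:, 1])
            rows_het.extend(ds.het)
        if bad:
            raise ValueError(f"no compatible diplotype for individuals {bad[:20]}")
        self.n = n
        self.ind = np.asarray(rows_ind)
        self.h1 = np.asarray(rows_h1)
        self.h2 = np.asarray(rows_h2)
        self.het = np.asarray(rows_het, dtype=bool)
        H = len(universe)
        self.counts = np.zeros((len(self.ind), H))
        np.add.at(self.counts, (np.arange(len(self.ind)), self.h1), 1.0)
        np.add.at(self.counts, (np.arange(len(self.ind)), self.h2), 1.0)
        # contiguous per-individual segments for reduceat
        assert np.all(np.diff(self.ind) >= 0)
        self.starts = np.searchsorted(self.ind, np.arange(n))
        self.present = np.zeros(H, dtype=bool)
        self.present[self.h1] = True
        self.present[self.h2] = True

    def log_prior(self, freqs: np.ndarray) -> np.ndarray:
        lp = np.log(np.maximum(freqs[self.h1], 1e-300)) + np.log(
            np.maximum(freqs[self.h2], 1e-300)
        )
        return lp + np.where(self.het, np.log(2.0), 0.0)

    def rowsum_to_ind(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts)

    def logsumexp_to_ind(self, logv: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduceat(logv, self.starts)
        return np.log(self.rowsum_to_ind(np.exp(logv - mx[self.ind]))) + mx

    def naive_freqs(self) -> np.ndarray:
        """Initial frequencies: equal weight over each individual's pairs."""
        k = np.diff(np.append(self.starts, len(self.ind)))
        w = 1.0 / k[self.ind]
        counts = (self.counts * w[:, None]).sum(axis=0)
        p = counts / (2 * self.n)
        return p / p.sum()


def _effect_design(exp_: _Expansion, ref_idx: int, covariates: np.ndarray | None):
    """Design matrix on expanded rows: intercept, non-ref haplotype counts, covariates."""
    H = len(exp_.universe)
    eff_cols = [h for h in range(H) if h != ref_idx and exp_.present[h]]
    dropped = [h for h in range(H) if h != ref_idx and not exp_.present[h]]
    X = [np.ones(len(exp_.ind)), *[exp_.counts[:, h] for h in eff_cols]]
    if covariates is not None:
        X.extend(covariates[exp_.ind, c] for c in range(covariates.shape[1]))
    return np.column_stack(X), eff_cols, dropped


# ---------------------------------------------------------------------------
# fit results


@dataclass
class _HaploFitBase:
    model: HaplotypeModel  # fitted frequencies (+ effects) packaged as a model
    universe: tuple[Haplotype, ...]
    reference: Haplotype
    freqs: np.ndarray
    effects: np.ndarray  # per-haplotype, reference = 0, NaN where dropped
    se: np.ndarray  # same layout
    covariate_names: list[str]
    covariate_coefs: np.ndarray
    intercept: float
    log_likelihood: float
    n_iter: int
    converged: bool
    n: int
    posterior: np.ndarray = field(repr=False)  # expanded-row posteriors
    _expansion: _Expansion = field(repr=False, default=None)

    def expected_haplotype_counts(self) -> np.ndarray:
        """Posterior-expected per-individual haplotype counts (rows sum to 2).

        The posterior is informed by the phenotype through the E-step.
        """
        e = self._expansion
        out = np.zeros((self.n, len(self.universe)))
        np.add.at(out, (e.ind, e.h1), self.posterior)
        np.add.at(out, (e.ind, e.h2), self.posterior)
        return out

    def genotype_expected_counts(self) -> np.ndarray:
        """Expected haplotype counts given genotype and fitted frequencies only.

        Phenotype-free: the HWE prior under the fitted p, renormalised over
        each individual's compatible diplotypes.  This is the dosage used for
        the ANOVA F-test — a regressor that borrows the outcome would make
        the test anticonservative under the null.
        """
        e = self._expansion
        lp = e.log_prior(self.freqs)
        w = np.exp(lp - e.logsumexp_to_ind(lp)[e.ind])
        out = np.zeros((self.n, len(self.universe)))
        np.add.at(out, (e.ind, e.h1), w)
        np.add.at(out, (e.ind, e.h2), w)
        return out

    def wald_p(self) -> np.ndarray:
        z = self.effects / self.se
        return 2.0 * norm.sf(np.abs(z))

    def frequency_percent(self) -> dict[str, float]:
        return {h.label: 100.0 * f for h, f in zip(self.universe, self.freqs)}


@dataclass
class HaploLinearFit(_HaploFitBase):
    sigma2: float = np.nan

    def summary_table(self) -> pd.DataFrame:
        p = self.wald_p()
        return pd.DataFrame(
            {
                "haplotype": [h.label for h in self.universe],
                "freq_pct": 100.0 * self.freqs,
                "effect": self.effects,
                "se": self.se,
                "p": p,
            }
        )


@dataclass
class HaploLogisticFit(_HaploFitBase):
    ascertainment_naive: bool = True  # frequencies estimated on the pooled sample

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.effects)

    def summary_table(self) -> pd.DataFrame:
        p = self.wald_p()
        lo = np.exp(self.effects - 1.96 * self.se)
        hi = np.exp(self.effects + 1.96 * self.se)
        return pd.DataFrame(
            {
                "haplotype": [h.label for h in self.universe],
                "freq_pct": 100.0 * self.freqs,
                "odds_ratio": self.odds_ratios(),
                "ci95_low": lo,
                "ci95_high": hi,
                "p": p,
            }
        )


def _check_small_counts(fit: _HaploFitBase) -> None:
    exp_counts = fit.expected_haplotype_counts().sum(axis=0)
    small = [
        h.label
        for h, c, present in zip(fit.universe, exp_counts, fit._expansion.present)
        if present and c < 5
    ]
    if small:
        warnings.warn(
            f"haplotypes with expected count < 5: {small}; their estimates are unstable"
        )


def _prep_covariates(covariates: pd.DataFrame | None) -> tuple[np.ndarray | None, list[str]]:
    if covariates is None:
        return None, []
    return covariates.to_numpy(dtype=float), [str(c) for c in covariates.columns]


# ---------------------------------------------------------------------------
# linear EM


def fit_haplo_linear(
    y: np.ndarray,
    snp_gt: np.ndarray,
    total_cn: np.ndarray,
    covariates: pd.DataFrame | None = None,
    universe: tuple[Haplotype, ...] | None = None,
    reference: Haplotype | str = "T/1",
    alt_allele: str = "C",
    tol: float = 1e-8,
    max_iter: int = 5000,
    compute_se: bool = True,
    null_model: bool = False,
) -> HaploLinearFit:
    """EM fit of the haplotype-specific linear regression.

    ``null_model=True`` freezes all haplotype effects at zero (covariates,
    sigma^2 and frequencies are still estimated) — the null of the LR test.
    """
    y = np.asarray(y, dtype=float)
    if universe is None:
        universe = haplotype_universe(alt_allele=alt_allele)
    ref = Haplotype.from_label(reference) if isinstance(reference, str) else reference
    ref_idx = universe.index(ref)
    exp_ = _Expansion(np.asarray(snp_gt), np.asarray(total_cn), universe, alt_allele)
    cov, cov_names = _prep_covariates(covariates)
    X, eff_cols, dropped = _effect_design(exp_, ref_idx, cov)
    q = len(eff_cols)
    if null_model:
        X = np.delete(X, np.s_[1 : 1 + q], axis=1)
    if dropped:
        warnings.warn(
            f"haplotypes absent from the data, coefficients dropped: "
            f"{[universe[h].label for h in dropped]}"
        )
    n = exp_.n
    n_params = X.shape[1] + 1 + (len(universe) - 1)
    if n <= n_params:
        raise ValueError(f"n={n} too small for {n_params} parameters")
    y_row = y[exp_.ind]

    p = exp_.naive_freqs()
    coef = np.zeros(X.shape[1])
    coef[0] = y.mean()
    sigma2 = float(np.var(y)) if np.var(y) > 0 else 1.0

    ll_prev = -np.inf
    converged = False
    w = None
    for it in range(1, max_iter + 1):
        mu = X @ coef
        log_lik_row = -0.5 * ((y_row - mu) ** 2 / sigma2 + np.log(sigma2) + _LOG2PI)
        logw = exp_.log_prior(p) + log_lik_row
        ll_i = exp_.logsumexp_to_ind(logw)
        ll = float(ll_i.sum())
        assert ll >= ll_prev - 1e-6 * max(1.0, abs(ll_prev)), "EM log-likelihood decreased"
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            w = np.exp(logw - ll_i[exp_.ind])
            ll_prev = ll
            break
        ll_prev = ll
        w = np.exp(logw - ll_i[exp_.ind])
        # M-step
        p = (exp_.counts * w[:, None]).sum(axis=0) / (2 * n)
        p = p / p.sum()
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y_row * sw, rcond=None)
        resid = y_row - X @ coef
        sigma2 = float((w * resid**2).sum() / n)
        sigma2 = max(sigma2, 1e-12)

    effects = np.zeros(len(universe))
    if not null_model:
        for k, h in enumerate(eff_cols):
            effects[h] = coef[1 + k]
    effects[dropped] = np.nan

    fit = HaploLinearFit(
        model=HaplotypeModel(
            haplotypes=universe, freqs=p, effects=np.nan_to_num(effects), reference=None
        ),
        universe=universe,
        reference=ref,
        freqs=p,
        effects=effects,
        se=np.full(len(universe), np.nan),
        covariate_names=cov_names,
        covariate_coefs=coef[(1 if null_model else 1 + q):],
        intercept=float(coef[0]),
        log_likelihood=ll_prev,
        n_iter=it,
        converged=converged,
        n=n,
        posterior=w,
        _expansion=exp_,
        sigma2=sigma2,
    )
    if not converged:
        warnings.warn(f"haplotype linear EM did not converge in {max_iter} iterations")
    if compute_se and not null_model:
        fit.se = _numeric_se_linear(fit, y_row, X, eff_cols, ref_idx)
    _check_small_counts(fit)
    return fit


def _pack_freq_logits(p: np.ndarray, ref_idx: int, free: list[int]) -> np.ndarray:
    return np.log(np.maximum(p[free], 1e-12) / max(p[ref_idx], 1e-12))


def _unpack_freqs(qv: np.ndarray, ref_idx: int, free: list[int], H: int) -> np.ndarray:
    p = np.zeros(H)
    p[ref_idx] = 1.0
    for k, h in enumerate(free):
        p[h] = np.exp(qv[k])
    return p / p.sum()


def _numeric_hessian(f, theta: np.ndarray, h_scale: float = 1e-3) -> np.ndarray:
    d = len(theta)
    h = h_scale * (1.0 + np.abs(theta))
    H = np.empty((d, d))
    f0 = f(theta)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _se_from_observed_loglik(obs_ll, theta: np.ndarray, n_eff_cols: int) -> np.ndarray:
    Hm = _numeric_hessian(obs_ll, theta)
    info = -Hm
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    var = np.diag(cov)[1 : 1 + n_eff_cols]
    return np.sqrt(np.maximum(var, 0.0))


def _numeric_se_linear(fit: HaploLinearFit, y_row, X, eff_cols, ref_idx) -> np.ndarray:
    exp_ = fit._expansion
    H = len(fit.universe)
    free = [h for h in range(H) if h != ref_idx and exp_.present[h]]
    q = len(eff_cols)
    ncov = X.shape[1] - 1 - q
    theta0 = np.concatenate(
        [
            [fit.intercept],
            [fit.effects[h] for h in eff_cols],
            fit.covariate_coefs,
            [0.5 * np.log(fit.sigma2)],
            _pack_freq_logits(fit.freqs, ref_idx, free),
        ]
    )

    def obs_ll(theta: np.ndarray) -> float:
        coef = theta[: 1 + q + ncov]
        sigma2 = np.exp(2.0 * theta[1 + q + ncov])
        p = _unpack_freqs(theta[2 + q + ncov :], ref_idx, free, H)
        mu = X @ coef
        logw = exp_.log_prior(p) - 0.5 * (
            (y_row - mu) ** 2 / sigma2 + np.log(sigma2) + _LOG2PI
        )
        return float(exp_.logsumexp_to_ind(logw).sum())

    se_eff = _se_from_observed_loglik(obs_ll, theta0, q)
    se = np.full(H, np.nan)
    for k, h in enumerate(eff_cols):
        se[h] = se_eff[k]
    return se


# ---------------------------------------------------------------------------
# logistic EM


def _weighted_bernoulli_ll(X, s, w, coef) -> float:
    eta = np.clip(X @ coef, -30.0, 30.0)
    return float((w * (s * eta - np.log1p(np.exp(eta)))).sum())


def _weighted_logistic_newton(
    X: np.ndarray, s: np.ndarray, w: np.ndarray, coef0: np.ndarray,
    tol: float = 1e-10, max_iter: int = 50,
) -> np.ndarray:
    """Newton ascent with step halving: never lowers the weighted log-likelihood."""
    coef = coef0.copy()
    ll = _weighted_bernoulli_ll(X, s, w, coef)
    for _ in range(max_iter):
        eta = np.clip(X @ coef, -30.0, 30.0)
        pi = expit(eta)
        grad = X.T @ (w * (s - pi))
        Wr = w * pi * (1.0 - pi)
        Hm = (X * Wr[:, None]).T @ X
        try:
            step = np.linalg.solve(Hm + 1e-10 * np.eye(Hm.shape[0]), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hm, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            cand = coef + scale * step
            ll_new = _weighted_bernoulli_ll(X, s, w, cand)
            if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            scale *= 0.5
        else:
            break
        moved = np.max(np.abs(scale * step))
        coef, ll = cand, ll_new
        if moved < tol:
            break
    return coef


def fit_haplo_logistic(
    status: np.ndarray,
    snp_gt: np.ndarray,
    total_cn: np.ndarray,
    covariates: pd.DataFrame | None = None,
    universe: tuple[Haplotype, ...] | None = None,
    reference: Haplotype | str = "T/1",
    alt_allele: str = "C",
    tol: float = 1e-8,
    max_iter: int = 5000,
    compute_se: bool = True,
    null_model: bool = False,
    on_separation: str = "raise",
) -> HaploLogisticFit:
    """EM fit of the haplotype-specific logistic regression (prospective).

    Case-control sampling is handled prospectively: the intercept absorbs the
    ascertainment, the per-haplotype log-ORs are consistently estimated for a
    rare disease.  Haplotype frequencies are pooled-sample estimates and
    flagged ascertainment-naive.

    ``on_separation`` controls what happens when a haplotype's coefficient
    diverges (complete or quasi-complete separation, typically a rare
    haplotype absent from one class): ``"raise"`` (default) raises
    SeparationError naming it; ``"warn"`` warns once and lets the
    coefficient sit at the likelihood plateau, leaving the common-haplotype
    estimates usable.
    """
    if on_separation not in ("raise", "warn"):
        raise ValueError("on_separation must be 'raise' or 'warn'")
    s = np.asarray(status, dtype=float)
    if set(np.unique(s)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if s.min() == s.max():
        raise ValueError("both case and control classes must be present")
    if universe is None:
        universe = haplotype_universe(alt_allele=alt_allele)
    ref = Haplotype.from_label(reference) if isinstance(reference, str) else reference
    ref_idx = universe.index(ref)
    exp_ = _Expansion(np.asarray(snp_gt), np.asarray(total_cn), universe, alt_allele)
    cov, cov_names = _prep_covariates(covariates)
    X, eff_cols, dropped = _effect_design(exp_, ref_idx, cov)
    q = len(eff_cols)
    if null_model:
        X = np.delete(X, np.s_[1 : 1 + q], axis=1)
    if dropped:
        warnings.warn(
            f"haplotypes absent from the data, coefficients dropped: "
            f"{[universe[h].label for h in dropped]}"
        )
    n = exp_.n
    s_row = s[exp_.ind]

    p = exp_.naive_freqs()
    coef = np.zeros(X.shape[1])
    coef[0] = np.log(s.mean() / (1.0 - s.mean()))

    ll_prev = -np.inf
    converged = False
    sep_warned = False
    w = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ coef, -30.0, 30.0)
        log_lik_row = s_row * eta - np.log1p(np.exp(eta))
        logw = exp_.log_prior(p) + log_lik_row
        ll_i = exp_.logsumexp_to_ind(logw)
        ll = float(ll_i.sum())
        assert ll >= ll_prev - 1e-6 * max(1.0, abs(ll_prev)), "EM log-likelihood decreased"
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            w = np.exp(logw - ll_i[exp_.ind])
            ll_prev = ll
            break
        ll_prev = ll
        w = np.exp(logw - ll_i[exp_.ind])
        p = (exp_.counts * w[:, None]).sum(axis=0) / (2 * n)
        p = p / p.sum()
        coef = _weighted_logistic_newton(X, s_row, w, coef)
        if not null_model and q > 0 and np.max(np.abs(coef[1 : 1 + q])) > 25.0:
            idx = int(np.argmax(np.abs(coef[1 : 1 + q])))
            label = universe[eff_cols[idx]].label
            if on_separation == "raise":
                raise SeparationError(f"complete separation for haplotype {label}")
            if not sep_warned:
                warnings.warn(
                    f"quasi-complete separation for haplotype {label}; "
                    "its log-OR is at a likelihood plateau and unreliable"
                )
                sep_warned = True

    effects = np.zeros(len(universe))
    if not null_model:
        for k, h in enumerate(eff_cols):
            effects[h] = coef[1 + k]
    effects[dropped] = np.nan

    fit = HaploLogisticFit(
        model=HaplotypeModel(
            haplotypes=universe, freqs=p, log_or=np.nan_to_num(effects), reference=None
        ),
        universe=universe,
        reference=ref,
        freqs=p,
        effects=effects,
        se=np.full(len(universe), np.nan),
        covariate_names=cov_names,
        covariate_coefs=coef[(1 if null_model else 1 + q):],
        intercept=float(coef[0]),
        log_likelihood=ll_prev,
        n_iter=it,
        converged=converged,
        n=n,
        posterior=w,
        _expansion=exp_,
    )
    if not converged:
        warnings.warn(f"haplotype logistic EM did not converge in {max_iter} iterations")
    if compute_se and not null_model:
        fit.se = _numeric_se_logistic(fit, s_row, X, eff_cols, ref_idx)
    _check_small_counts(fit)
    return fit


def _numeric_se_logistic(fit: HaploLogisticFit, s_row, X, eff_cols, ref_idx) -> np.ndarray:
    exp_ = fit._expansion
    H = len(fit.universe)
    free = [h for h in range(H) if h != ref_idx and exp_.present[h]]
    q = len(eff_cols)
    ncov = X.shape[1] - 1 - q
    theta0 = np.concatenate(
        [
            [fit.intercept],
            [fit.effects[h] for h in eff_cols],
            fit.covariate_coefs,
            _pack_freq_logits(fit.freqs, ref_idx, free),
        ]
    )

    def obs_ll(theta: np.ndarray) -> float:
        coef = theta[: 1 + q + ncov]
        p = _unpack_freqs(theta[1 + q + ncov :], ref_idx, free, H)
        eta = np.clip(X @ coef, -30.0, 30.0)
        logw = exp_.log_prior(p) + s_row * eta - np.log1p(np.exp(eta))
        return float(exp_.logsumexp_to_ind(logw).sum())

    se_eff = _se_from_observed_loglik(obs_ll, theta0, q)
    se = np.full(H, np.nan)
    for k, h in enumerate(eff_cols):
        se[h] = se_eff[k]
    return se


def haplotype_frequencies_em(
    snp_gt: np.ndarray,
    total_cn: np.ndarray,
    universe: tuple[Haplotype, ...] | None = None,
    alt_allele: str = "C",
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> np.ndarray:
    """Genotype-only EM estimate of haplotype frequencies (no phenotype)."""
    if universe is None:
        universe = haplotype_universe(alt_allele=alt_allele)
    exp_ = _Expansion(np.asarray(snp_gt), np.asarray(total_cn), universe, alt_allele)
    p = exp_.naive_freqs()
    ll_prev = -np.inf
    for _ in range(max_iter):
        logw = exp_.log_prior(p)
        ll_i = exp_.logsumexp_to_ind(logw)
        ll = float(ll_i.sum())
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            break
        ll_prev = ll
        w = np.exp(logw - ll_i[exp_.ind])
        p = (exp_.counts * w[:, None]).sum(axis=0) / (2 * exp_.n)
        p = p / p.sum()
    return p


# ---------------------------------------------------------------------------
# downstream summaries


@dataclass
class VarianceReport:
    explained_fraction: float
    f_stat: float
    df_num: int
    df_den: int
    p: float


def anova_explained(
    fit: HaploLinearFit,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> VarianceReport:
    """F-test of the haplotype dosages against the covariates-only model.

    Compares OLS on [intercept, covariates] with OLS adding the expected
    non-reference haplotype dosages (genotype-based, phenotype-free); the
    explained fraction is (RSS_null - RSS_full) / RSS_null.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cov, _ = _prep_covariates(covariates)
    Xn = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    e_counts = fit.genotype_expected_counts()
    ref_idx = fit.universe.index(fit.reference)
    keep = [
        h for h in range(len(fit.universe)) if h != ref_idx and fit._expansion.present[h]
    ]
    q = len(keep)
    if q <= 0:
        raise ValueError("no non-reference haplotypes to test")
    Xf = np.column_stack([Xn, e_counts[:, keep]])
    rss_n = float(np.sum((y - Xn @ np.linalg.lstsq(Xn, y, rcond=None)[0]) ** 2))
    rss_f = float(np.sum((y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]) ** 2))
    df_den = n - Xf.shape[1]
    f_stat = ((rss_n - rss_f) / q) / (rss_f / df_den)
    p = float(f_dist.sf(f_stat, q, df_den))
    return VarianceReport(
        explained_fraction=(rss_n - rss_f) / rss_n,
        f_stat=float(f_stat),
        df_num=q,
        df_den=df_den,
        p=p,
    )


@dataclass
class LiabilityReport:
    v_obs: float
    prevalence: float
    z: float
    v_liab: float
    lr_stat: float | None = None
    df: int | None = None
    p: float | None = None


def liability_variance(v_obs: float, prevalence: float) -> LiabilityReport:
    """Observed-scale variance fraction mapped to the liability scale.

    V_liab = V_obs * K(1-K) / z^2, with z the standard-normal density at the
    upper-K threshold.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if v_obs < 0:
        raise ValueError("observed-scale variance fraction must be >= 0")
    t = norm.isf(prevalence)
    z = float(norm.pdf(t))
    v_liab = v_obs * prevalence * (1.0 - prevalence) / z**2
    return LiabilityReport(v_obs=v_obs, prevalence=prevalence, z=z, v_liab=v_liab)


def lr_test(loglik_full: float, loglik_null: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test: returns (statistic, p) with p = chi^2_df upper tail."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if loglik_full < loglik_null - 1e-6:
        raise ValueError(
            f"full-model log-likelihood ({loglik_full}) below null ({loglik_null}); "
            "models are misordered"
        )
    stat = max(0.0, 2.0 * (loglik_full - loglik_null))
    return stat, float(chi2_dist.sf(stat, df))
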