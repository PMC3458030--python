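"""Single-marker dosage association, conditional tests, lambda_GC, meta-analysis.

Dosage regression is ordinary least squares of the phenotype on the marker
dosage plus covariates, with a two-sided Wald test on the dosage coefficient.
Dosages may be integer MAP calls or real posterior means: copy-number dosages
range over [0, 4], SNP allele dosages over [0, 2], and tri-allelic #A - #B
dosages over [-2, 2].  Conditional analysis appends conditioning markers to
the covariates.  The genomic-control inflation factor is the median
association chi-square divided by the null chi^2_1 median, and studies
combine by fixed-effect inverse-variance weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

__all__ = [
    "MarkerDosage",
    "AssocResult",
    "dosage_regression",
    "conditional_regression",
    "genomic_lambda",
    "inverse_variance_meta",
]

_KIND_RANGES = {"cnp": (0.0, 4.0), "snp": (0.0, 2.0), "triallelic": (-2.0, 2.0)}

_P_FLOOR = 5e-324  # smallest positive float: keeps p in (0, 1] under underflow


def _floor_p(p: float) -> float:
    return max(float(p), _P_FLOOR)

CHI2_1_MEDIAN = chi2.ppf(0.5, 1)  # 0.45493642...


@dataclass
class MarkerDosage:
    """Per-individual real dosage for one marker, with its declared kind."""

    values: np.ndarray
    kind: str = "snp"
    marker_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KIND_RANGES:
            raise ValueError(f"unknown dosage kind {self.kind!r}")
        lo, hi = _KIND_RANGES[self.kind]
        if np.nanmin(self.values) < lo - 1e-9 or np.nanmax(self.values) > hi + 1e-9:
            raise ValueError(
                f"dosage values outside the {self.kind} range [{lo}, {hi}]"
            )


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    n: int
    marker_id: str = ""
    covariate_set: str = ""

    def chi2_stat(self) -> float:
        return (self.beta / self.se) ** 2


class CollinearityError(ValueError):
    pass


def _design(
    dosage: MarkerDosage,
    covariates: pd.DataFrame | None,
    extra: list[MarkerDosage] | None = None,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(dosage.values)), dosage.values]
    names = ["intercept", dosage.marker_id or "dosage"]
    for c in extra or []:
        cols.append(c.values)
        names.append(c.marker_id or f"conditioner{len(names)}")
    if covariates is not None:
        for name in covariates.columns:
            cols.append(covariates[name].to_numpy(dtype=float))
            names.append(str(name))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        offending = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise CollinearityError(f"design matrix is rank deficient; collinear columns: {offending}")
    return X, names


def dosage_regression(
    y: np.ndarray,
    dosage: MarkerDosage,
    covariates: pd.DataFrame | None = None,
    covariate_set: str = "",
) -> AssocResult:
    """OLS of y on [intercept, dosage, covariates]; Wald test on the dosage."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(dosage.values):
        raise ValueError("phenotype and dosage lengths differ")
    mask = np.isfinite(y) & np.isfinite(dosage.values)
    if covariates is not None:
        mask &= np.isfinite(covariates.to_numpy(dtype=float)).all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} rows with missing values (listwise deletion)")
        y = y[mask]
        dosage = MarkerDosage(dosage.values[mask], dosage.kind, dosage.marker_id)
        covariates = covariates.loc[mask] if covariates is not None else None
    X, _ = _design(dosage, covariates)
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=_floor_p(fit.pvalues[1]),
        n=len(y),
        marker_id=dosage.marker_id,
        covariate_set=covariate_set,
    )


def conditional_regression(
    y: np.ndarray,
    target: MarkerDosage,
    conditioners: list[MarkerDosage],
    covariates: pd.DataFrame | None = None,
    covariate_set: str = "",
) -> AssocResult:
    """Wald test on the target dosage adjusting for conditioning markers.

    With an empty conditioner list this is exactly ``dosage_regression``.
    Raises CollinearityError (never a silent NA) if the target is collinear
    with a conditioner.
    """
    y = np.asarray(y, dtype=float)
    X, _ = _design(target, covariates, extra=conditioners)
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=_floor_p(fit.pvalues[1]),
        n=len(y),
        marker_id=target.marker_id,
        covariate_set=covariate_set,
    )


def genomic_lambda(p_values: np.ndarray | None = None, chi2_stats: np.ndarray | None = None) -> float:
    """Genomic-control inflation factor: median chi^2_1 statistic / 0.4549...

    Supply either two-sided p-values (converted via the inverse upper tail of
    chi^2_1) or the chi-square statistics themselves.
    """
    if chi2_stats is None:
        if p_values is None:
            raise ValueError("supply p-values or chi-square statistics")
        p_values = np.asarray(p_values, dtype=float)
        if p_values.size == 0:
            raise ValueError("empty input")
        chi2_stats = chi2.isf(p_values, 1)
    chi2_stats = np.asarray(chi2_stats, dtype=float)
    if chi2_stats.size == 0:
        raise ValueError("empty input")
    if chi2_stats.size < 100:
        warnings.warn(
            f"lambda_GC from only {chi2_stats.size} markers; >= 100 recommended"
        )
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)


def inverse_variance_meta(results: list[tuple[float, float]]) -> AssocResult:
    """Fixed-effect meta-analysis of (beta, se) pairs.

    beta_hat = sum(w beta)/sum(w), se = 1/sqrt(sum w) with w = 1/se^2; Wald p.
    """
    if not results:
        raise ValueError("no studies to combine")
    betas = np.array([b for b, _ in results], dtype=float)
    ses = np.array([s for _, s in results], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = _floor_p(2.0 * norm.sf(abs(z)))
    return AssocResult(beta=beta, se=se, p=p, n=len(results))
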