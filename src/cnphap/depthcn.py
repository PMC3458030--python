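"""Integer copy-number calls from depth of coverage.

Pipeline: per-sample normalisation of raw depth by chromosome-mean coverage
(times two, so diploid samples centre at 2), a rank-1 SVD score summarising
each sample's depth over the candidate region, and a one-dimensional Gaussian
mixture fitted to the scores with the number of components chosen by BIC.
Mixture components map to integer copy numbers by anchoring the modal
(largest-weight) component at copy number 2 — most samples are diploid-normal
— and stepping by one per adjacent component in mean order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "NormalizedDepth",
    "GaussianMixture1D",
    "CNCallSet",
    "normalize_depth",
    "region_score",
    "fit_gmm_1d",
    "call_cn_gmm",
    "loess_smooth",
]


@dataclass
class NormalizedDepth:
    """Depth normalised per sample to centre at 2 for diploid copy number."""

    positions: np.ndarray
    values: np.ndarray  # (n, m)

    def region(self, start: int, end: int) -> np.ndarray:
        """Submatrix over [start, end) in base coordinates."""
        mask = (self.positions >= start) & (self.positions < end)
        return self.values[:, mask]


def normalize_depth(raw: np.ndarray, chrom_mean: np.ndarray, positions: np.ndarray | None = None) -> NormalizedDepth:
    """out[i, j] = 2 * raw[i, j] / chrom_mean[i].

    ``chrom_mean`` is each sample's mean coverage over the whole chromosome;
    a sample whose depth equals its mean everywhere maps to 2 everywhere.
    """
    raw = np.asarray(raw, dtype=float)
    chrom_mean = np.asarray(chrom_mean, dtype=float)
    bad = np.flatnonzero(chrom_mean <= 0)
    if bad.size:
        raise ValueError(f"non-positive chromosome mean for sample indices {bad.tolist()}")
    if positions is None:
        positions = np.arange(raw.shape[1])
    return NormalizedDepth(positions=np.asarray(positions), values=2.0 * raw / chrom_mean[:, None])


def region_score(region_depth: np.ndarray) -> np.ndarray:
    """Per-sample loading on the leading rank-1 factor of the region submatrix.

    The score is the leading left-singular-vector entry scaled by the leading
    singular value (so it carries the magnitude of the depth signal), with the
    sign oriented so that score correlates positively with each sample's mean
    depth over the region.
    """
    X = np.asarray(region_depth, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("region must span >= 2 samples and >= 2 bases")
    if not np.any(X):
        raise ValueError("all-zero region submatrix")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, 0] * s[0]
    row_means = X.mean(axis=1)
    if np.std(scores) > 0 and np.std(row_means) > 0:
        if np.corrcoef(scores, row_means)[0, 1] < 0:
            scores = -scores
    elif scores.sum() < 0:  # degenerate (identical rows): orient nonnegative
        scores = -scores
    return scores


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture by EM


@dataclass
class GaussianMixture1D:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool

    @property
    def k(self) -> int:
        return len(self.means)

    def bic(self, n: int) -> float:
        return -2.0 * self.log_likelihood + (3 * self.k - 1) * np.log(n)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        lp = (
            np.log(self.weights)[None, :]
            + norm.logpdf(x[:, None], self.means[None, :], self.sds[None, :])
        )
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))


class EMNonConvergence(RuntimeError):
    """EM failed to converge; ``best_fit`` carries the last iterate."""

    def __init__(self, message: str, best_fit: GaussianMixture1D):
        super().__init__(message)
        self.best_fit = best_fit


def _em_1d(x: np.ndarray, means0: np.ndarray, tol: float, max_iter: int) -> GaussianMixture1D:
    k = len(means0)
    n = len(x)
    means = means0.copy()
    spread = np.std(x) if np.std(x) > 0 else 1.0
    sds = np.full(k, spread / max(k, 1) + 1e-6)
    weights = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    var_floor = max(1e-10, (1e-4 * spread) ** 2)
    for it in range(1, max_iter + 1):
        lp = np.log(weights)[None, :] + norm.logpdf(x[:, None], means[None, :], sds[None, :])
        lse = logsumexp(lp, axis=1)
        ll = float(lse.sum())
        # EM guarantee, checked every step (tiny float slack)
        assert ll >= ll_prev - 1e-8 * max(1.0, abs(ll_prev)), "EM log-likelihood decreased"
        r = np.exp(lp - lse[:, None])
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
        if ll - ll_prev < tol * max(1.0, abs(ll)) and it > 1:
            return GaussianMixture1D(means, sds, weights, ll, it, True)
        ll_prev = ll
    return GaussianMixture1D(means, sds, weights, ll_prev, max_iter, False)


def fit_gmm_1d(
    x: np.ndarray,
    k: int,
    seed,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GaussianMixture1D:
    """Fit a k-component 1-D Gaussian mixture by EM with seeded random restarts."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = np.asarray(x, dtype=float)
    best: GaussianMixture1D | None = None
    # deterministic quantile init first, then random restarts; duplicate
    # starting means collapse components, so fall back to unique values
    ux = np.unique(x)
    q0 = np.quantile(x, (np.arange(k) + 0.5) / k)
    if len(np.unique(q0)) < k and len(ux) >= k:
        q0 = ux[np.linspace(0, len(ux) - 1, k).round().astype(int)]
    inits = [q0]
    pool = ux if len(ux) >= k else x
    for _ in range(n_restarts - 1):
        inits.append(np.sort(rng.choice(pool, size=k, replace=len(pool) < k)))
    for m0 in inits:
        fit = _em_1d(x, np.asarray(m0, dtype=float), tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    if not best.converged:
        raise EMNonConvergence(
            f"1-D GMM EM did not converge in {max_iter} iterations (k={k})", best
        )
    order = np.argsort(best.means)
    return GaussianMixture1D(
        best.means[order], best.sds[order], best.weights[order],
        best.log_likelihood, best.n_iter, best.converged,
    )


@dataclass
class CNCallSet:
    """Integer copy-number calls with the mixture fit behind them."""

    scores: np.ndarray
    cn: np.ndarray  # MAP integer copy number per sample
    mixture: GaussianMixture1D
    component_cn: np.ndarray  # copy number assigned to each mixture component
    posteriors: np.ndarray  # (n, k) component posteriors

    @property
    def posterior_mean_cn(self) -> np.ndarray:
        """Posterior-mean copy-number dosage (real-valued), for dosage tests."""
        return self.posteriors @ self.component_cn.astype(float)


def call_cn_gmm(
    scores: np.ndarray,
    seed,
    max_components: int = 5,
    max_cn: int = 4,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> CNCallSet:
    """Fit mixtures with k = 1..max_components, pick min BIC, call integer CN.

    Components (ordered by mean) map to copy numbers by anchoring the modal
    component at cn = 2 and stepping +-1 per neighbour, clipped to
    [0, max_cn]; calls are maximum a posteriori.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to fit a mixture")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best: GaussianMixture1D | None = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        if k > len(np.unique(scores)):
            break
        try:
            fit = fit_gmm_1d(scores, k, rng, tol=tol, max_iter=max_iter)
        except EMNonConvergence:
            continue
        b = fit.bic(len(scores))
        if b < best_bic - 1e-9:  # ties break toward smaller k
            best, best_bic = fit, b
    if best is None:
        raise RuntimeError("no mixture model converged")
    modal = int(np.argmax(best.weights))
    component_cn = np.clip(2 + np.arange(best.k) - modal, 0, max_cn)
    post = best.responsibilities(scores)
    cn = component_cn[np.argmax(post, axis=1)]
    return CNCallSet(
        scores=scores, cn=cn, mixture=best, component_cn=component_cn, posteriors=post
    )


def loess_smooth(positions: np.ndarray, values: np.ndarray, window: int = 2000) -> np.ndarray:
    """Local-regression smoother of one sample's depth track (plotting only).

    Simple tricube-weighted local linear fit over a fixed base-pair window;
    never used in the inference path.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    half = window / 2.0
    for i, p in enumerate(positions):
        m = np.abs(positions - p) <= half
        d = np.abs(positions[m] - p) / half
        w = (1 - d**3) ** 3
        X = np.column_stack([np.ones(m.sum()), positions[m] - p])
        W = w[:, None]
        beta, *_ = np.linalg.lstsq(X * W, values[m] * w, rcond=None)
        out[i] = beta[0]
    return out
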