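"""Common-deletion breakpoint estimation from a depth/copy-number correlation track.

At each base j, the Pearson correlation r_j between per-sample normalised
depth and the inferred integer copy number measures whether that base lies
inside the shared deletion.  The statistic S_j = n * r_j^2 is asymptotically
chi-square with one degree of freedom: central (lambda = 0) outside the
deleted segment, noncentral with lambda > 0 inside it.  A two-state hidden
Markov model — Null (central chi^2_1) and Alt (noncentral chi^2_1(lambda)) —
with a tiny symmetric switching probability tau is fitted by Baum-Welch, the
Viterbi path delimits the deleted segment, and parametric-bootstrap
refits give percentile confidence intervals for each breakpoint.

All HMM arithmetic runs in log space: at tau = 1e-250 nothing else survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, ncx2

__all__ = [
    "CorrelationTrack",
    "BreakpointHMM",
    "BreakpointResult",
    "correlation_statistic",
    "fit_breakpoint_hmm",
    "viterbi_path",
    "call_breakpoints",
]

LOG_FLOOR = -745.0  # log-density clip against exp underflow
_S_FLOOR = 1e-12  # chi^2_1 density diverges at 0; keep S strictly positive


@dataclass
class CorrelationTrack:
    """Per-base correlation r_j and statistic S_j = n * r_j^2."""

    positions: np.ndarray  # 0-based
    r: np.ndarray
    s: np.ndarray
    n: int
    zero_variance: np.ndarray = field(default=None)  # bases with constant depth

    def __post_init__(self) -> None:
        if self.zero_variance is None:
            self.zero_variance = np.zeros(len(self.r), dtype=bool)


def correlation_statistic(depth: np.ndarray, cn: np.ndarray, positions: np.ndarray | None = None) -> CorrelationTrack:
    """Pearson r at each base between normalised depth and integer CN calls.

    Bases where depth has zero variance across samples get r = 0 and are
    flagged.  Requires >= 3 samples and a non-constant CN vector.
    """
    depth = np.asarray(depth, dtype=float)
    cn = np.asarray(cn, dtype=float)
    n, m = depth.shape
    if n < 3:
        raise ValueError("need >= 3 individuals for a correlation track")
    if np.all(cn == cn[0]):
        raise ValueError("copy-number calls are all identical; correlation undefined")
    if positions is None:
        positions = np.arange(m)
    c = cn - cn.mean()
    d = depth - depth.mean(axis=0, keepdims=True)
    sd_d = np.sqrt((d**2).sum(axis=0))
    zero_var = sd_d == 0
    denom = np.where(zero_var, 1.0, sd_d) * np.sqrt((c**2).sum())
    r = (d * c[:, None]).sum(axis=0) / denom
    r[zero_var] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return CorrelationTrack(
        positions=np.asarray(positions), r=r, s=n * r**2, n=n, zero_variance=zero_var
    )


# ---------------------------------------------------------------------------
# two-state HMM with central/noncentral chi^2_1 emissions


def _log_emissions(s: np.ndarray, lam: float) -> np.ndarray:
    """(T, 2) log emission densities: column 0 Null (central), 1 Alt (lambda)."""
    s = np.maximum(s, _S_FLOOR)
    log_null = chi2.logpdf(s, df=1)
    if lam > 1e-12:
        log_alt = ncx2.logpdf(s, df=1, nc=lam)
    else:
        log_alt = log_null.copy()
    out = np.column_stack([log_null, log_alt])
    return np.maximum(out, LOG_FLOOR)


def _forward_backward(log_b: np.ndarray, log_pi: np.ndarray, log_a: np.ndarray):
    """Log-space forward-backward. Returns (log-likelihood, gamma, xi_sum)."""
    T = log_b.shape[0]
    la = log_a
    alpha = np.empty((T, 2))
    beta = np.empty((T, 2))
    alpha[0] = log_pi + log_b[0]
    for t in range(1, T):
        m = alpha[t - 1][:, None] + la  # (from, to)
        alpha[t] = np.logaddexp(m[0], m[1]) + log_b[t]
    ll = float(np.logaddexp(alpha[-1, 0], alpha[-1, 1]))
    beta[-1] = 0.0
    for t in range(T - 2, -1, -1):
        m = la + (log_b[t + 1] + beta[t + 1])[None, :]
        beta[t] = np.logaddexp(m[:, 0], m[:, 1])
    lg = alpha + beta - ll
    gamma = np.exp(lg)
    # expected transition counts (not needed while tau is fixed, returned for
    # completeness/diagnostics)
    xi_sum = np.zeros((2, 2))
    if T > 1:
        for i in range(2):
            for j in range(2):
                v = alpha[:-1, i] + la[i, j] + log_b[1:, j] + beta[1:, j] - ll
                xi_sum[i, j] = np.exp(v).sum()
    return ll, gamma, xi_sum


@dataclass
class BreakpointHMM:
    """Fitted two-state (Null/Alt) HMM over a correlation track."""

    tau: float
    lam: float
    log_pi: np.ndarray
    posteriors: np.ndarray  # (T, 2), columns Null/Alt
    log_likelihood: float
    ll_trace: np.ndarray
    n_iter: int
    converged: bool
    degenerate: bool = False

    @property
    def log_a(self) -> np.ndarray:
        return np.log(
            np.array([[1.0 - self.tau, self.tau], [self.tau, 1.0 - self.tau]])
        )


def _lambda_mstep(s: np.ndarray, w: np.ndarray, lam_prev: float) -> float:
    """M-step for the Alt noncentrality.

    Moment update lambda = max(0, weighted mean of S - 1) — the mean of
    chi^2_1(lambda) is 1 + lambda — refined by a bounded 1-D maximisation of
    the expected complete-data log-likelihood.  The previous lambda stays a
    candidate, so the update never lowers the Q function (generalised EM,
    monotone observed log-likelihood).
    """
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    lam0 = max(0.0, float((w * s).sum() / wsum) - 1.0)

    s_pos = np.maximum(s, _S_FLOOR)

    def negq(lam: float) -> float:
        if lam < 1e-12:
            lb = chi2.logpdf(s_pos, df=1)
        else:
            lb = ncx2.logpdf(s_pos, df=1, nc=lam)
        return -float((w * np.maximum(lb, LOG_FLOOR)).sum())

    res = minimize_scalar(
        negq, bounds=(max(1e-8, lam0 * 0.5), max(1.0, lam0 * 2.0)), method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [lam_prev, lam0, 0.0]
    if res.success:
        candidates.append(float(res.x))
    return min(candidates, key=negq)


def fit_breakpoint_hmm(
    track: CorrelationTrack,
    tau: float = 1e-250,
    seed=None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> BreakpointHMM:
    """Baum-Welch fit of the two-state chi^2 HMM; tau stays fixed.

    Estimates the Alt noncentrality lambda and the state prior; the observed
    log-likelihood is nondecreasing across iterations (asserted).  A track
    with no signal at all (all S = 0) returns an all-Null fit with lambda = 0.
    """
    if len(track.s) == 0:
        raise ValueError("empty correlation track")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    s = np.asarray(track.s, dtype=float)
    if np.all(s <= _S_FLOOR):
        T = len(s)
        post = np.column_stack([np.ones(T), np.zeros(T)])
        return BreakpointHMM(
            tau=tau, lam=0.0, log_pi=np.log([1.0 - 1e-12, 1e-12]),
            posteriors=post, log_likelihood=float(chi2.logpdf(_S_FLOOR, 1) * T),
            ll_trace=np.array([]), n_iter=0, converged=True, degenerate=True,
        )
    log_a = np.log(np.array([[1.0 - tau, tau], [tau, 1.0 - tau]]))
    # init: prior 50/50; lambda from the upper decile of S
    log_pi = np.log([0.5, 0.5])
    hi = s[s >= np.quantile(s, 0.9)]
    lam = max(1.0, float(hi.mean()) - 1.0)
    ll_prev = -np.inf
    trace = []
    converged = False
    gamma = None
    for it in range(1, max_iter + 1):
        log_b = _log_emissions(s, lam)
        ll, gamma, _ = _forward_backward(log_b, log_pi, log_a)
        assert ll >= ll_prev - 1e-6 * max(1.0, abs(ll_prev)), "HMM log-likelihood decreased"
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        # M-step: state prior and Alt noncentrality (transitions fixed)
        pi = np.maximum(gamma[0], 1e-300)
        log_pi = np.log(pi / pi.sum())
        lam = _lambda_mstep(s, gamma[:, 1], lam)
    return BreakpointHMM(
        tau=tau, lam=lam, log_pi=log_pi, posteriors=gamma,
        log_likelihood=ll_prev, ll_trace=np.array(trace), n_iter=len(trace),
        converged=converged,
    )


def viterbi_path(hmm: BreakpointHMM, track: CorrelationTrack) -> np.ndarray:
    """Maximum-likelihood state path (0 = Null, 1 = Alt), in log space."""
    s = np.asarray(track.s, dtype=float)
    log_b = _log_emissions(s, hmm.lam)
    la = hmm.log_a
    T = len(s)
    delta = np.empty((T, 2))
    back = np.zeros((T, 2), dtype=int)
    delta[0] = hmm.log_pi + log_b[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + la
        back[t] = np.argmax(cand, axis=0)
        delta[t] = cand[back[t], [0, 1]] + log_b[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def path_log_probability(hmm: BreakpointHMM, track: CorrelationTrack, path: np.ndarray) -> float:
    """Log joint probability of (path, observations) under the fitted HMM."""
    s = np.asarray(track.s, dtype=float)
    log_b = _log_emissions(s, hmm.lam)
    lp = hmm.log_pi[path[0]] + log_b[0, path[0]]
    la = hmm.log_a
    for t in range(1, len(path)):
        lp += la[path[t - 1], path[t]] + log_b[t, path[t]]
    return float(lp)


@dataclass
class AltRun:
    left: int  # 1-based inclusive
    right: int
    length: int


@dataclass
class BreakpointResult:
    """Deletion boundaries (1-based inclusive) with bootstrap 95% CIs."""

    status: str  # "ok" or "no deletion detected"
    left: int | None
    right: int | None
    left_ci: tuple[int, int] | None
    right_ci: tuple[int, int] | None
    path: np.ndarray
    runs: list[AltRun]
    lam: float

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "left": self.left,
            "right": self.right,
            "left_ci_95": list(self.left_ci) if self.left_ci else None,
            "right_ci_95": list(self.right_ci) if self.right_ci else None,
            "lambda": self.lam,
            "n_alt_runs": len(self.runs),
            "runs": [{"left": r.left, "right": r.right, "length": r.length} for r in self.runs],
        }


def _alt_runs(path: np.ndarray, positions: np.ndarray) -> list[AltRun]:
    runs = []
    in_run = False
    start = 0
    for t, st in enumerate(path):
        if st == 1 and not in_run:
            in_run, start = True, t
        elif st == 0 and in_run:
            runs.append(AltRun(int(positions[start]) + 1, int(positions[t - 1]) + 1, t - start))
            in_run = False
    if in_run:
        runs.append(
            AltRun(int(positions[start]) + 1, int(positions[len(path) - 1]) + 1, len(path) - start)
        )
    return runs


def call_breakpoints(
    hmm: BreakpointHMM,
    track: CorrelationTrack,
    n_boot: int = 100,
    seed=None,
    boot_max_iter: int = 200,
) -> BreakpointResult:
    """Viterbi breakpoints plus parametric-bootstrap percentile 95% CIs.

    Bootstrap: resample S_j from the fitted two-state model conditional on the
    ML path (central chi^2_1 where Null, chi^2_1(lambda) where Alt), refit and
    re-call; the 2.5/97.5 percentiles of the re-called boundaries form the CI.
    Multiple Alt runs are all reported, the longest flagged primary.
    """
    path = viterbi_path(hmm, track)
    runs = _alt_runs(path, track.positions)
    if not runs:
        return BreakpointResult(
            status="no deletion detected", left=None, right=None,
            left_ci=None, right_ci=None, path=path, runs=[], lam=hmm.lam,
        )
    runs.sort(key=lambda r: -r.length)
    primary = runs[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lefts, rights = [], []
    for _ in range(n_boot):
        s_boot = np.where(
            path == 1,
            ncx2.rvs(df=1, nc=max(hmm.lam, 1e-12), size=len(path), random_state=rng),
            chi2.rvs(df=1, size=len(path), random_state=rng),
        )
        bt = CorrelationTrack(
            positions=track.positions, r=np.sqrt(np.minimum(s_boot / track.n, 1.0)),
            s=s_boot, n=track.n,
        )
        bfit = fit_breakpoint_hmm(bt, tau=hmm.tau, tol=1e-8, max_iter=boot_max_iter)
        bruns = _alt_runs(viterbi_path(bfit, bt), track.positions)
        if bruns:
            bruns.sort(key=lambda r: -r.length)
            lefts.append(bruns[0].left)
            rights.append(bruns[0].right)
    if lefts:
        l_lo, l_hi = np.percentile(lefts, [2.5, 97.5]).astype(int)
        r_lo, r_hi = np.percentile(rights, [2.5, 97.5]).astype(int)
        left_ci = (min(l_lo, primary.left), max(l_hi, primary.left))
        right_ci = (min(r_lo, primary.right), max(r_hi, primary.right))
    else:
        left_ci = right_ci = None
    return BreakpointResult(
        status="ok", left=primary.left, right=primary.right,
        left_ci=left_ci, right_ci=right_ci, path=path, runs=runs, lam=hmm.lam,
    )
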