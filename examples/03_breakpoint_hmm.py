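"""Estimate shared deletion breakpoints with the chi-square HMM.

At each base, n * r^2 (r = correlation of normalised depth with the called
copy number) is central chi^2_1 outside the deleted segment and noncentral
inside it.  A two-state HMM with switching probability 1e-250 is fitted by
Baum-Welch; the Viterbi path delimits the deletion, and a parametric
bootstrap gives 95% confidence intervals for each breakpoint.
"""

from cnphap import depthcn, presets
from cnphap.breakhmm import call_breakpoints, correlation_statistic, fit_breakpoint_hmm
from cnphap.synthcohort import DepthSimConfig, collapse_genotypes, draw_diplotypes, simulate_depth

model = presets.cpd_gwas_model()
dipl = draw_diplotypes(model, 89, seed=11)
_, cn = collapse_genotypes(dipl, model)

cfg = DepthSimConfig(start=0, end=12_000, del_start=5_000, del_end=8_000, mean_coverage=6.0)
dm = simulate_depth(cn, cfg, seed=12)
nd = depthcn.normalize_depth(dm.depth, dm.chrom_mean, dm.positions)

track = correlation_statistic(nd.values, cn, nd.positions)
hmm = fit_breakpoint_hmm(track, tau=1e-250)
result = call_breakpoints(hmm, track, n_boot=50, seed=13)

print(f"estimated noncentrality lambda: {hmm.lam:.1f}  (n = {track.n})")
print(f"breakpoints (1-based inclusive): {result.left:,} - {result.right:,}")
print(f"95% CI left : {result.left_ci[0]:,} - {result.left_ci[1]:,}")
print(f"95% CI right: {result.right_ci[0]:,} - {result.right_ci[1]:,}")
print(f"simulated truth                : {cfg.del_start + 1:,} - {cfg.del_end:,}")
print("Lambda near n means depth and copy number are almost perfectly")
print("correlated inside the deletion; the CIs span a handful of bases.")
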