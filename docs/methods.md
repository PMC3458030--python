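# Methods

## Scope and design

`cnphap` implements the locus-scale statistical chain for a common copy-number
polymorphism analysed jointly with a tag SNP: six haplotypes (SNP allele
T/C × haplotypic copy number 0/1/2), phase-ambiguous collapsed genotypes,
and haplotype-resolved association for a quantitative trait (CPD) and
case-control traits. Everything runs on synthetic cohorts whose generative
parameters are the published haplotype tables (`cnphap.presets`), so each
stage is testable against known truth. Genome-wide scans, array-intensity
genotyping, reference-panel imputation engines and PCA are out of scope; the
package consumes PC covariates, it does not derive them.

## Synthetic cohorts (`synthcohort`)

Diplotypes are drawn under Hardy–Weinberg random mating: two i.i.d. draws
from the haplotype frequency vector per individual. No inbreeding parameter
is offered — the EM models downstream assume the same HWE diplotype prior,
and the generator deliberately matches the analysis assumptions so that
estimator bias, not model mismatch, is what the tests measure.

Quantitative phenotype: y = xᵀγ + β_{h1} + β_{h2} + ε, ε ~ Normal(0, σ_e²).
The published table gives effects in cigarettes/day but no phenotypic SD;
we derive σ_e = 16.9, the value at which the six-haplotype component
explains 1.83% of phenotypic variance under the published frequencies and
effects — the explained-variance figure reported for that cohort. CPD is
kept continuous by default (an integer-rounding/zero-truncation switch
exists but is off): the trait is analysed as a linear-model response, and
rounding only adds a discretisation term the published analysis does not
model.

Disease status: P(case) = expit(α + Σ_h θ_h n_h + xᵀγ) with θ the log of
the published odds ratios. α is solved by root-finding so the enumerated
diplotype distribution gives a target prevalence (1% for the case-control
recovery studies — the diseases involved are of roughly that order and, at
low prevalence, the control haplotype frequencies used as population truth
are internally consistent). Exact case/control counts are sampled without
replacement from a simulated population of 150,000 (≥1,300 expected cases at
1%, comfortably above the largest study's 997).

Covariates default to sex ~ Bernoulli(0.5), age ~ Normal(55, 10) truncated
at 20 (age² derived), cessation ~ Bernoulli(0.4), two PCs ~ Normal(0, 1),
all with zero effect unless configured — distributions are unstated in the
source material, so the defaults are typical of a middle-aged smoking
cohort and deliberately inert.

Read depth: raw counts with mean coverage × cn/2 inside the deletion and
× 1 outside; Poisson noise by default with a configurable variance/mean
overdispersion (gamma–Poisson). Each sample also gets a chromosome-mean
coverage simulated from a large diploid background (default 2 Mb), because
normalisation in practice divides by a whole-chromosome mean in which a
~30 kb deletion is negligible; normalising by the *window* mean instead
would leak copy number into the off-deletion baseline. What the generator
does **not** emulate: GC and mappability waves, alignment artefacts,
batch-varying coverage profiles, partial/atypical deletion alleles, genotype
calling from array intensities. Passing tests therefore demonstrate correct
statistics under the stated model, not robustness to real sequencing
artefacts.

## Copy-number inference (`depthcn`)

Normalised depth is 2·raw/mean_chrom. The candidate-region score is the
leading left-singular-vector loading scaled by the leading singular value
(sign oriented to correlate positively with row means): a rank-1 summary
that pools all bases of the region into one number per sample. A 1-D
Gaussian mixture is fitted to the scores by EM (10 seeded restarts,
relative tolerance 1e-8, ≤500 iterations, per-iteration likelihood-ascent
assertion); k = 1..5 are fitted and the BIC minimum chosen, ties toward
smaller k. Components map to integer copy numbers by ordering on the mean
and anchoring the largest-weight component at cn = 2 — most samples are
diploid — stepping ±1 per neighbour (clipped at 0); calls are MAP. The
anchor rule fails by construction if the diploid class is not modal; the
mixture summary (means, weights, mapping) is always reported so that
pathological cohorts are visible. A LOESS-style smoother is provided for
depth plots only and never enters inference.

## Breakpoint HMM (`breakhmm`)

Per base, r_j is the Pearson correlation across samples between normalised
depth and the integer CN call; S_j = n·r_j² is asymptotically χ²₁, central
outside the shared deletion and noncentral (λ > 0) inside. The two-state
HMM fixes the symmetric switching probability τ = 1e−250 (configurable);
at that magnitude all arithmetic is in log space, with log-densities
floored at −745 and S floored at 1e−12 (the χ²₁ density diverges at 0).
Baum–Welch re-estimates the state prior and λ; the λ M-step starts from the
moment estimate max(0, weighted-mean(S) − 1) (the χ²₁(λ) mean is 1 + λ) and
refines it by a bounded 1-D maximisation of the expected complete-data
log-likelihood, keeping the previous λ as a candidate — a generalised-EM
update, so the observed log-likelihood is nondecreasing (asserted every
iteration). Convergence: relative change < 1e−10 or 1,000 iterations.

Breakpoints are the first/last base of the maximal-length Alt run of the
Viterbi path (1-based inclusive in all reports; 0-based half-open
internally, conversions only at the I/O boundary). Multiple Alt runs are
all reported with the longest flagged primary. 95% CIs come from a
parametric bootstrap: S_j resampled from the fitted two-state model
conditional on the ML path, refit, re-called, percentile interval (widened
to contain the point estimate when the bootstrap distribution is degenerate
at a few bases). The bootstrap is a pragmatic construction — the CI method
behind the published breakpoint intervals is not described — so coverage is
verified by simulation (≥17/20 replicates in the suite) rather than assumed.
Zero-depth-variance bases get r = 0 and are flagged; correlations are
computed at every base.

## Tri-allelic coding and phasing (`delimpute`)

Inside a common deletion a SNP has alleles {A, B, O}. Recoding from a
diploid-style call plus region copy number: cn 0 → (O,O); cn 1 → (A,O) or
(B,O) (a heterozygous diploid call with one surviving copy is an
inconsistency error); cn 2 homozygous → (A,A)/(B,B), heterozygous →
unknown (the phase of A/B over the two copies is unobservable). The dosage
is #A − #B ∈ [−2, 2] with O contributing 0; imputed genotypes contribute
their posterior expectation (a best-guess alternative would discard the
calibrated uncertainty the EM provides).

The phaser enumerates the haplotype space exhaustively (≤12 markers), with
the O allele atomic per haplotype across the deletion interval — one shared
deletion, no partial alleles. Standard haplotype-frequency EM follows
(uniform initialisation over observed-compatible haplotypes, tolerance
1e−8, ≤2,000 iterations, frequencies < 1e−6 pruned at output); an optional
per-individual copy-number constraint fixes the number of O-carrying
haplotypes to 2 − cn. This is a locus-scale stand-in for a general
multi-allelic imputation engine, sufficient for the deletion-aware coding
that is the point; it has no recombination model and no reference-panel
machinery.

## Association utilities (`assoc`)

Dosage regression is OLS of phenotype on [intercept, dosage, covariates]
with a two-sided Wald test (statsmodels). Dosage kinds declare their range
(cnp 0–4, snp 0–2, tri-allelic −2..2); real-valued posterior-mean dosages
are accepted for single-marker tests, while the haplotype analysis consumes
integer MAP calls. Conditional analysis appends conditioning markers to the
design and errors loudly on collinearity (never a silent NA). λ_GC is the
median χ²₁ statistic divided by 0.45494 (the exact χ²₁ median via scipy);
meta-analysis is fixed-effect inverse-variance. Missing data: listwise
deletion with a warning; covariates are never imputed.

## Haplotype-specific regression (`haploreg`)

The E-step weights each compatible diplotype by HWE prior × outcome
likelihood; the M-step updates frequencies from expected haplotype counts
/2n, coefficients by weighted least squares (linear) or Newton with step
halving (logistic; the halving guarantees the weighted Bernoulli likelihood
never decreases, preserving EM ascent, asserted every iteration), and σ²
from the weighted residual sum of squares /n. Initialisation: frequencies
by equal-weight counting over compatible diplotypes, effects 0, σ² =
var(y); tolerance 1e−8 relative, ≤5,000 iterations. Haplotypes absent from
every compatible diplotype are dropped with a warning; haplotypes with
expected count < 5 are flagged as unstable. Standard errors are the inverse
numerically differentiated observed-data information (central differences,
step 1e−3·(1+|θ|), over coefficients, log σ and frequency logits jointly).

Case-control data are fitted prospectively: the intercept absorbs
ascertainment and the log-ORs are consistent for a rare disease; the
frequencies are pooled-sample quantities and flagged ascertainment-naive.
Complete separation (typically a ~0.2% haplotype absent from one class)
raises an error naming the haplotype by default; `on_separation="warn"`
instead leaves that coefficient at its likelihood plateau so the common
haplotypes remain estimable in simulation studies.

ANOVA explained variance compares covariates-only OLS against OLS adding
the expected non-reference haplotype dosages, F = ((RSS₀−RSS₁)/q)/(RSS₁/(n−p));
the explained fraction is relative to the covariate-adjusted phenotype
variance. The dosages here are **genotype-based** expectations (HWE prior
under the fitted frequencies, no phenotype term): a regressor that borrows
the outcome through the E-step posterior makes the null F-test visibly
anticonservative, which a zero-effect pipeline check confirmed; with
phenotype-free dosages the test is calibrated and the GWAS-scale explained
variance is essentially unchanged (the dominant ambiguity class resolves
almost entirely on the prior).

Liability-threshold transform: V_liab = V_obs·K(1−K)/z², z the standard
normal density at the upper-K threshold. K defaults to the sample case
fraction and should be overridden with a population prevalence when one is
known — published liability-variance figures depend on an unstated
prevalence, so they are not recovery targets here. The LR test compares the
full EM fit against the same model with effects frozen at zero (frequencies
and covariates still estimated), statistic 2Δℓ against χ² with one df per
estimated haplotype effect.

## Pipeline and I/O (`pipeline`, `io`)

`run_study` chains simulate → depth-call → breakpoints → dosage association
(marginal + conditional) → haplotype regression, with every random draw
descending from one seed and every output carrying a hash of the scientific
configuration. Reports are byte-identical across reruns; wall-clock stage
timings go to a separate run log. bedGraph is 0-based half-open per the
format standard; printed positions are 1-based inclusive. VCF input (via
cyvcf2) covers biallelic SNP records only — symbolic deletion records are
not parsed.

## Problem sizes and reproduction

The parameter-recovery studies (`recovery`, driven by
`scripts/acceptance.py`) use the published study sizes directly: n = 11,696
for the quantitative cohort, 982/4,480 and 997/6,491 for the case-control
studies, sampled from 150,000-person populations at 1% prevalence. Averages
use 10 seeds (quantitative) and 15 seeds (case-control), sized so the
Monte-Carlo standard error of each averaged estimate — e.g. 0.29/√10 for
the deletion-haplotype effect — is small against the generative value.
Odds ratios are averaged on the log scale (geometric mean): the arithmetic
mean of exp(β̂) is biased upward by ~exp(se²/2). Simulation-based test
checks (bootstrap coverage, LR calibration, type-I error) run at reduced
replicate counts with acceptance bands expressed in the matching binomial
or KS units.

## Known limitations

- All EM fits assume HWE diplotype priors; structured or inbred cohorts
  violate this and the frequency estimates will absorb the deviation.
- The depth model has no positional covariates (GC, mappability), so the
  breakpoint HMM's base-exact accuracy here is an upper bound on real data.
- The breakpoint CI construction is a bootstrap stand-in, validated by
  simulated coverage only.
- Logistic haplotype frequencies are pooled case-control estimates; for
  strongly ascertained designs only the log-ORs should be interpreted.
- The phaser's exhaustive enumeration caps at 12 markers by design.
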