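# cnphap

Copy-number/SNP haplotype analysis of a common-deletion locus, built around
the genetics of the *CYP2A6* region: a ~30 kb deletion polymorphism common in
the Japanese population that, together with a nearby tag SNP, forms six
haplotypes with strong effects on smoking intensity (cigarettes per day, CPD)
and smoking-related disease risk.

The package is for statistical geneticists who want a tested, end-to-end
implementation of this analysis style — copy-number genotyping from read
depth, deletion breakpoint mapping, deletion-aware marker coding, and
haplotype-resolved association — exercised entirely on synthetic cohorts, so
every stage can be validated against known generative truth without any
controlled-access data.

## The model

Each haplotype is a pair (SNP allele, haplotypic copy number) with allele
T/C and copy number 0/1/2 — six haplotypes in all. An assay observes only
the collapsed genotype: the diploid SNP genotype g ∈ {0,1,2} and the total
copy number c ∈ {0..4}. Several diplotypes (unordered haplotype pairs) can be
compatible with one observation; treating the diplotype *d* as latent, the
haplotype-specific regression is

    y | d ~ Normal( μ + Σ_h β_h n_h(d) + xᵀγ, σ² )          (quantitative)
    s | d ~ Bernoulli( expit( μ + Σ_h θ_h n_h(d) + xᵀγ ) )  (case-control)
    P(d | p) = p_{h1} p_{h2} (×2 if h1 ≠ h2)                 (HWE prior)

with β (or log-odds-ratio θ) fixed at 0 for the reference haplotype. All
parameters — frequencies p, effects, covariate coefficients, σ² — are
jointly estimated by EM on the observed-data likelihood Σ_d P(d|p)·f(y|d);
standard errors come from the numerically differentiated observed-data
log-likelihood.

Upstream of the regression:

- **Copy-number calls from depth** (`depthcn`): per-sample depth normalised
  by chromosome-mean coverage (×2, so diploid ≡ 2), samples scored by the
  leading SVD factor of the candidate region, and a 1-D Gaussian mixture
  (BIC-selected k) fitted to the scores, the modal component anchored at
  copy number 2.
- **Breakpoints** (`breakhmm`): at base j, S_j = n·r_j² (r_j = correlation of
  depth with called copy number) is central χ²₁ outside the deleted segment
  and noncentral χ²₁(λ) inside it; a two-state HMM with switching
  probability τ = 1e−250 is fitted by Baum–Welch, the Viterbi path delimits
  the deletion, and a parametric bootstrap gives breakpoint CIs.
- **Tri-allelic coding** (`delimpute`): SNPs inside the deletion get a third
  allele O; observed calls recode deterministically given the region copy
  number, unknowns are imputed by an exhaustive-enumeration EM phaser, and
  association uses the #A − #B dosage in [−2, 2].
- **Association utilities** (`assoc`): dosage regression with covariates,
  conditional tests, genomic-control λ, inverse-variance meta-analysis.

The synthetic-data module (`synthcohort`) generates all of it — HWE
diplotypes from published frequency tables, additive phenotypes, logistic
disease status with exact case/control counts, and Poisson read depth over a
deletion-bearing window — reproducibly from a single seed.

## Worked example

`examples/05_haplotype_regression.py` simulates a GWAS-scale CPD cohort
(n = 11,696, the published six-haplotype model as generative truth) and
fits the EM linear model on the collapsed genotypes:

```
haplotype  freq_pct  effect    se     p
      T/0    19.467  -4.312 0.313 0.000
      T/1    41.015   0.000   NaN   NaN
      T/2     0.261  -0.927 3.288 0.778
      C/0     0.845  -6.461 1.579 0.000
      C/1    38.120  -2.525 0.256 0.000
      C/2     0.292  -3.362 2.969 0.257
explained variance: 2.00%  (generating value 1.83%), F p = 5.54e-49
```

The deletion haplotype T/0 (19.5% frequency, −4.3 cigarettes/day) and the
mutant haplotype C/1 (38.1%, −2.5) are recovered from phase-ambiguous data;
the reference row is the baseline, and rare haplotypes (<1%) carry the large
standard errors their counts imply. The same script fits the COPD
case-control model (982 cases / 4,480 controls) and recovers the protective
odds ratios (T/0 ≈ 0.19 vs generating 0.20; C/1 ≈ 0.41 vs 0.38).

The other examples cover cohort simulation, depth-based copy-number calling
(`02`, 100% call accuracy at 6× coverage), HMM breakpoint mapping (`03`,
boundaries exact to the base with few-base CIs), tri-allelic imputation
(`04`), conditional association and meta-analysis (`06`), and the one-call
pipeline (`07`).

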