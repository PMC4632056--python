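# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `hwimpute`, together with what the synthetic-data
generator does and does not emulate.

## Model and tests

### The f-parameterized genotype model

A biallelic marker with allele frequency p_A (p_B = 1 − p_A) and
within-population inbreeding coefficient f has genotype probabilities

    P_AA = p_A² + p_A p_B f,  P_AB = 2 p_A p_B (1 − f),  P_BB = p_B² + p_A p_B f,

admissible for −p_m/(1 − p_m) ≤ f ≤ 1 with p_m = min(p_A, p_B). f = 0 is
HWE; f > 0 a heterozygote deficit; the lower bound zeroes the minor
homozygote class. The ML estimator from a multinomial sample of genotype
counts is f̂ = (4 n_AA n_BB − n_AB²)/(n_A n_B). The numerator and
denominator are formed in exact integer arithmetic before the final
division, so the estimator is exact to one rounding for n up to at least
10⁷.

The asymptotic variance, derived from the inverse Fisher information of
the (p_A, f) parameterization and verified against the empirical sampling
variance of f̂ in simulation, is

    Var(f̂) = (1 − f)²(1 − 2f)/n + f(1 − f)(2 − f)/(2 n p_A p_B),

which is 1/n at f = 0 and 0 at f = 1. Inference uses the **null variance
1/n** by default. The plug-in variance (estimates substituted) is exposed
behind a flag but not recommended: it typically falls below 1/n, making
the Wald test liberal, and degenerates to zero whenever a sample has no
heterozygotes (f̂ = 1), which is common at low minor allele frequency.

The χ² test statistic is X² = n f̂² with 1 df, **without continuity
correction** — the identity with the Pearson statistic holds only for the
uncorrected form (verified against Σ(O−E)²/E in the tests). The signed
deviate z = sign(f̂)√X² = √n·f̂ has unit variance under the null.

### Exact test and the mid p-value

Conditional on the allele count n_A, the heterozygote count under HWE
follows the Levene–Haldane distribution, supported on the k of the same
parity as n_A with 0 ≤ k ≤ min(n_A, n_B). It is evaluated in log space
via log-gamma, stable to at least n = 10⁵, and renormalized only to
absorb rounding at the 1e−12 level; the test suite checks every
distribution with n ≤ 200 against exact rational enumeration.

One-sided p-values: the deficiency tail sums P(k ≤ observed), the excess
tail P(k ≥ observed); the *mid* versions give the observed outcome half
weight. The mid excess p-value is **derived** as one minus the deficiency
value rather than recomputed, so the complement identity holds bit-for-
bit. Two-sided: the standard convention sums all outcomes as likely or
less likely than the observed one; the mid convention takes half the
observed probability plus strictly less likely outcomes. "As likely" is
decided on log-probabilities with relative tolerance 1e−12, because plain
floating equality is platform-dependent. Conditioning is on the allele as
labeled (VCF REF); all results are invariant to the label swap (tested).

Monomorphic markers (n_A = 0 or n_B = 0) return p = 1 with a flag rather
than raising, so batch pipelines never abort.

### Rubin's rules

Pooling m per-imputation results: mean estimate, within-variance W (mean
of per-imputation variances; exactly 1 for z statistics and probit-
transformed p-values), between-variance B with the m − 1 divisor, total
T = W + (1 + 1/m)B, and ν = (m − 1)(1 + mW/((m + 1)B))². Degrees of
freedom follow the classical formula only — no small-sample
(Barnard–Rubin) truncation. When B < 1e−14 the imputations are treated as
identical and the reference distribution is the standard normal (the
ν → ∞ limit); this makes pooling of m copies of the same p-value an exact
round trip.

One-sided exact mid p-values are combined on the probit scale,
z_i = Φ⁻¹(1 − p_i). Before transforming, p is clamped to
[tiny, 1 − eps] where tiny is the smallest positive normal double and
eps the machine epsilon of 1, so z_i is always finite even for markers
with vanishingly small p-values. The pooled deficiency p-value is the
upper t_ν tail of z̄/√T; excess is its complement (bit-exact); the
two-sided MI p-value 2·min of the pair can never exceed one. The tail
convention is fixed to deficiency throughout; the mid p-value (never
exactly 1 for polymorphic data) is what makes the probit transform
usable at low minor allele frequency. T keeps the full (1 + 1/m)B
inflation with W fixed at 1, i.e. the pooling rules are applied to the
z_i exactly as to estimates.

Note the two two-sided conventions deliberately differ: the complete-data
exact test reports the "as likely or less likely" sum, while the MI test
reports 2·min of the one-sided p-values (the sign of z cannot be
recovered from a two-sided p-value, so the MI combination is inherently
one-sided). For a marker with no missing values the one-sided pooled
p-values equal the complete-data one-sided mid p-values exactly; the
two-sided values agree only between like conventions.

## Imputation model

One incomplete target marker; covariates assumed complete for the samples
to be imputed (when they are not, the model is declared inestimable and
the fallback chain advances — the behavior observed on real arrays where
flanking markers are missing for the same individuals). A multinomial
logit of the genotype category on:

- `flanking`: two indicator columns per flank (heterozygote and
  alternate-homozygote, reference-homozygote base). Categorical coding is
  used because dosage linearity of the flank effect is an extra
  assumption we do not need.
- `intensities`: the two channels as linear terms.
- `flanking+intensities`: both.

The fit maximizes the complete-case log-likelihood penalized by
independent N(0, 2.5²) priors on all coefficients (Newton with step
halving on the strictly concave penalized objective; built on the
statsmodels MNLogit likelihood machinery). The weakly-informative prior
is the standard remedy for quasi-separation, which is routine with
categorical predictors and sparse flank-pattern cells: without it, half
the fits on realistic panels fail to converge and fall back to marginal
imputation, wasting the covariate information. Scale 2.5 follows common
weakly-informative practice for logit coefficients; results are
insensitive to moderate changes because the likelihood dominates in
estimable cells. *Perfect* separation — covariates that classify every
complete case with near-certainty (minimum self-category probability
above 0.95) — is still reported as inestimable, since the unpenalized
likelihood has no interior maximum and imputations would merely echo the
covariates.

Each imputation round draws a coefficient vector from the Laplace
(normal) approximation to the coefficient posterior — mean at the
posterior mode, covariance the inverse penalized observed information —
then samples one genotype per missing entry from the implied category
probabilities. This propagates parameter uncertainty, making the
imputations proper; with a single incomplete variable and complete
covariates no chained iteration is needed, one draw per round suffices.
The model can impute only categories observed at the marker; when one
homozygote is absent from the data it is never produced, a known
limitation of category-level imputation.

The marginal fallback draws category probabilities from a Dirichlet over
the observed category counts (a proper posterior draw under a
multinomial-Dirichlet model restricted to observed categories) and always
succeeds for polymorphic data; a monomorphic observed response is filled
with its single category and flagged inestimable. The fallback used is
recorded per marker (`model_used`) so downstream users can filter.

Seed policy: one master seed per run; per-marker seeds are a 31-bit
keyed hash of (master seed, marker id), so marker-level results are
reproducible independently of batch order and composition.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:
genotypes i.i.d. from the f-model; flanking markers that copy the target
genotype with probability `ld_r` and are resampled from its empirical
marginal otherwise (a single interpretable LD knob — haplotype
simulation is deliberately out of scope); two-channel intensities from
per-genotype Gaussian clusters with an optional near-origin null-allele
cluster; and missingness that is MCAR, heterozygote-biased (base rate
times a multiplier ≥ 1 for heterozygotes, reflecting the middle cloud
bordering both homozygote clouds on arrays), or driven by a latent null
allele whose carriers are all missing with near-zero intensities.

Defaults describe a SNP-array cohort: 1939 samples, 677 markers, allele
frequency drawn uniformly on [0.05, 0.95] per marker (no minor-allele-
frequency threshold; the uniform sampler is a pluggable default, not an
estimate of any particular array's frequency spectrum), 5% MCAR
missingness, ld_r = 0.8, cluster means at (1.0, 0.1), (0.6, 0.6),
(0.1, 1.0) with spread 0.15 and a null cluster at (0.02, 0.02) with
spread 0.02. Intensity spread 0.15 leaves realistic cluster overlap;
perfectly separated clusters would make any intensity-based logit
inestimable by construction.

What the generator does **not** emulate — and hence what passing tests do
not establish about real arrays: genotyping error (heterozygotes
miscalled as homozygotes), copy-number variation, haplotype-level LD
structure, batch effects, and informative missingness beyond the three
mechanisms above. Calibration and recovery results here are statements
about the assumed model, not about any particular platform.

## Numerical choices

- Probability-tie tolerance in two-sided exact tests: 1e−12 relative on
  log-probabilities.
- Between-variance degeneracy threshold: B < 1e−14 → normal limit.
- p-value clamping: [smallest positive normal double, 1 − machine
  epsilon of 1].
- Coefficient-prior scale 2.5; Newton tolerance 1e−8 on the max gradient
  component, at most 100 iterations; posterior draws use the SVD method
  so a numerically semi-definite covariance cannot abort a batch.
- The exact-distribution cache keys on (n, n_A), so panel-scale testing
  at a common sample size reuses each conditional distribution.

## Problem sizes used in the checks

Simulation-based checks in the test suite use: 10,000 replicate markers
(n = 100, p_A = 0.3) for null calibration of the mid-p exact test;
500 markers (n = 500, f = 0.1, ld_r = 0.8, 20% MCAR, m = 10) for MI
recovery against discarding; 677-marker, 1939-sample panels for
uniformity of the null p-value distribution; and exhaustive rational-
arithmetic verification of every exact conditional distribution with
n ≤ 200. These sizes are the package's own validation choices and match
the regimes the defaults describe.

## Known limitations

- Only biallelic autosomal markers; no X-chromosome or multi-allelic
  exact tests.
- The imputer cannot produce genotypes never observed at the marker, so
  false heterozygote excess caused by a missing homozygote class cannot
  be corrected, only flagged.
- The MI two-sided p-value is 2·min of one-sided tests, which is
  conservative relative to the complete-data sum convention for highly
  asymmetric conditional distributions.
- Flanking covariates are taken from the two nearest markers by physical
  position, with no check that the LD is actually informative; an
  uninformative flank simply yields imputations close to marginal.
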