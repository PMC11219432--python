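# Methods

## The problem

In cohorts of people with a progressive disease (the motivating case is
Parkinson's disease, with motor severity measured by the MDS-UPDRS part III),
disease course is naturally summarised by a linear multilevel model: each
individual has an intercept (severity at diagnosis) and a slope (points of
worsening per year).  `mrtraj` implements two-sample Mendelian Randomisation
(2SMR) where the *outcome* of the MR is this pair — the causal effect of an
exposure on severity at diagnosis and on the rate of progression, estimated
jointly.

Two-sample design: the SNP–exposure effects γ_k come from an external GWAS
and are treated as fixed and known; the SNP–outcome effects are estimated in
the progression cohort.

## Models

### Per-SNP progression model

For each instrument k the cohort model is a random-intercept/random-slope
linear mixed model:

    y_ij = β0k + u0i + β1k·G_ik + (β2k + u1i + β3k·G_ik)·t_ij + ε_ij,

with G_ik ∈ {0,1,2} the allele count, (u0i, u1i) ~ N(0, Ψ),
ε_ij ~ N(0, σ²).  The quantities carried forward are the SNP–intercept
effect β̂1k, the SNP–slope effect β̂3k, and their joint 2×2 covariance
(the off-diagonal is not negligible: with the default generating values the
implied correlation is about −0.35).

If the exposure X satisfies X_i = γ0k + γ_k·G_ik + error, substituting into
the structural progression model shows β1k = α1·γ_k and β3k = α4·γ_k, where
α1 and α4 are the causal effects of X on intercept and slope.  This
proportionality across SNPs is what the meta-regression stage exploits.

### MR estimators

* **Naive**: two separate fixed-effect IVW meta-regressions — a weighted
  no-intercept regression of β̂1k (resp. β̂3k) on γ_k with weights
  1/Var(β̂1k) (resp. 1/Var(β̂3k)).  Closed form:
  α̂ = Σ w_k γ_k β̂_k / Σ w_k γ_k², Var(α̂) = 1/Σ w_k γ_k².
* **Multivariate**: a stacked fixed-effects GLS over the 2-vectors
  β̂_k = (β̂1k, β̂3k)ᵀ with design X_k = γ_k·I₂ and weight matrix
  S_k⁻¹, the inverse of each SNP's full 2×2 covariance:
  α̂ = (Σ γ_k² S_k⁻¹)⁻¹ Σ γ_k S_k⁻¹ β̂_k, with
  Var(α̂) = (Σ γ_k² S_k⁻¹)⁻¹.

Both are fixed-effect estimators with the meta-regression residual variance
forced to 1 — no overdispersion or underdispersion scaling — matching
standard 2SMR weighting.  The point estimates of the two approaches are
nearly identical; the multivariate approach additionally delivers the
covariance between α̂1 and α̂4, which is what joint regions and the
effect-over-time band need.

Cohort-level estimates can be pooled across studies by fixed-effects
multivariate meta-analysis (precision weighting with the full 2×2
covariances), and a joint Wald test χ² = α̂ᵀV⁻¹α̂ on 2 df tests "the
exposure has no effect on either intercept or slope".

### Confidence regions

* Separate Wald intervals per dimension, α̂ ± 1.959964·SE at 95%.
* Joint rectangle: the Cartesian product of the two intervals.  For
  independent estimates its joint coverage is ≈ 0.95² = 0.9025 — this is the
  motivation for proper joint regions.
* Confidence ellipse {θ : (θ−α̂)ᵀV⁻¹(θ−α̂) ≤ q} with q = χ²₂(0.95) =
  5.991465, either with the full covariance (multivariate) or with the
  off-diagonal zeroed (naive ellipse).  Area = π·q·√det V; by Hadamard's
  inequality the full-covariance ellipse is never larger than the
  zero-covariance one at matched marginal variances.
* Effect-over-time band: effect(t) = α̂1 + α̂4·t with pointwise variance
  v11 + 2t·v12 + t²·v22.  With the typical negative v12 the full-covariance
  band is strictly narrower than the independence band at every t > 0 (the
  variance difference is 2t·v12).  Default grid 0–6 in 0.1 steps, the
  simulated follow-up window.

All regions are closed (boundary counts as contained) — a measure-zero
convention fixed for determinism.

## Synthetic cohort generator

The generator emulates an MDS-UPDRS-III-like progression cohort:

    y_ij = α0 + u0i + α1·X_i + α2·C_i + (α3 + u1i + α4·X_i + α5·C_i)·t_ij + ε_ij

| parameter | meaning | default |
|---|---|---|
| α0 | intercept grand mean (outcome points) | 24 |
| α1 | exposure→intercept (points per exposure SD) | 2 |
| α2 | confounder→intercept (points per confounder SD) | 1 |
| α3 | slope grand mean (points/year) | 2.25 |
| α4 | exposure→slope (points/year per SD) | 0.45 |
| α5 | confounder→slope (points/year per SD) | 0.225 |
| Ψ | random-effects covariance | [[88.9, −6.0], [−6.0, 4.6]] |
| σ² | level-1 residual variance | 51.9 |
| n | individuals | 10,000 (sensitivity design: 1,000) |
| R² | exposure variance explained by instruments | 0.10 or 0.02 |

Components:

* **Instruments**: 97 independent SNPs.  The motivating BMI GWAS hit table is
  not redistributable, so the default table is synthetic: effect-allele
  frequencies uniform on [0.05, 0.95], per-allele effect magnitudes from a
  right-skewed Gamma(shape 2) with random signs, rescaled so the total
  genetic variance Σ γ_k²·2p_k(1−p_k) equals 0.05 exactly.  The constant is
  arbitrary because the exposure is standardised — only R² matters.  Any
  user-supplied TSV (snp_id, eaf, gamma) can be used instead.
* **Genotypes**: dosages Binomial(2, eaf), independent across SNPs (no LD).
* **Exposure/confounder**: raw exposure = Σ γ_k G_ik + b·C_i + e_i, with
  C ~ N(0,1).  The residual variance is genetic_variance·(1−R²)/R², split
  half to the confounder (b² = half) and half to independent noise, so the
  confounder explains 50% of the residual exposure variance.  X is divided
  by its *expected* SD √(genetic_variance/R²); the per-allele effects on
  this standardised exposure, γ_k/sd_expected, are exported and used by the
  MR stage.  This per-SD convention makes the estimands (α1, α4) identical
  at R² = 2% and 10%.
* **Visit schedules**: balanced — 7 visits at exact times 0..6 years;
  unbalanced (sensitivity design) — 1/2/3/4 visits with probabilities
  0.2/0.3/0.3/0.2, baseline time Uniform(0, 3.5) (recruitment within 3.5
  years of diagnosis), gaps Uniform(1.4, 1.6) (≈18-month visits).  No
  truncation of follow-up is imposed.
* **Scenarios**: 1 is the baseline above; 2 halves the slope effects
  (α4 = 0.25, α5 = 0.125); 3 zeroes both slope effects (α4 = α5 = 0);
  4 zeroes both intercept effects (α1 = α2 = 0); 5 and 6 flip the
  random-effects covariance to +6.0 and +12.0, flipping the sign of the
  per-SNP effect correlation.  In scenarios 3 and 4 the confounder effect on
  the affected dimension is zeroed together with the exposure effect.

What the generator does **not** emulate: linkage disequilibrium between
instruments, pleiotropy (all SNPs act only through the exposure — the IV
assumptions hold by construction), index-event/collider bias from selecting
on diagnosis, informative drop-out, measurement error, non-linear
trajectories, or time-varying exposures.  Passing simulation results
therefore certify the estimator's behaviour when its assumptions hold, not
robustness to their violation.

All randomness descends from a single scenario seed through named
`SeedSequence` substreams (instruments, genotypes, confounder,
exposure-noise, schedule, random-effects, residuals), so each component can
be regenerated in isolation and every table is exactly replicable.

## Mixed-model fitting

The simulation study refits the per-SNP model 97 × (number of replicates)
times, so the fitter is written for this shape of problem:

* Maximum likelihood by default (REML behind a flag); the fixed-effect
  estimates are insensitive to the choice at these sample sizes, and the
  criterion used is recorded in the fit metadata.
* The deviance is profiled over the fixed effects and σ², leaving a
  3-parameter optimisation over the log-Cholesky factor of Λ = Ψ/σ²
  (which guarantees Ψ positive-semidefinite).
* Because the random design (1, t) has rank 2, the Woodbury identity reduces
  every per-individual GLS quantity to cross-products ZᵀZ, Zᵀy, yᵀy computed
  once per cohort; each likelihood evaluation is a handful of vectorised 2×2
  operations, with cost independent of visit counts and identical for
  balanced and unbalanced designs.  The implementation is verified in the
  test suite against statsmodels MixedLM (independent route) and against a
  dense block-diagonal GLS oracle.
* Optimiser: Nelder–Mead, relative deviance tolerance 1e-8, parameter
  tolerance 1e-4, at most 200 iterations.  Within a cohort, SNP k+1 is
  warm-started at SNP k's variance components (a single SNP explains a tiny
  variance share, so the components barely move); the loop is deterministic.
* Non-convergence policy: flagged fits are excluded from both MR estimators
  identically and the count is reported — never imputed.  A constant dosage
  column raises an identifiability error.

## Simulation harness and performance measures

`run_study` runs replicates with seeds base_seed + index, holding one
instrument table fixed across replicates (the two-sample γ's are constants
of the design).  Per scenario × method × dimension it reports: mean
estimate, empirical SD, mean model SE, bias with Monte Carlo SE
(empirical SD/√n_reps), relative bias (reported as NA when the truth is
zero), and 95% CI coverage; jointly: rectangle, naive-ellipse and
multivariate-ellipse coverage and mean ellipse areas; plus the mean and SD
of the per-SNP effect correlation.  Failed replicates are counted and
disclosed, never silently dropped.

## Problem sizes used for verification

The package's own verification runs the study at reduced scale: cohorts of
n = 1,000 individuals with 97 SNPs, 100 replicates per scenario in the test
suite and 200 in the acceptance script (the reference design used n = 10,000
with 1,000 replicates).  At n = 1,000 the per-replicate sampling SD is √10
larger than at n = 10,000, so means and coverages are compared within
3 Monte Carlo standard errors computed from the actual run (binomial SE for
coverages), plus the rounding half-width of any reference value quoted at
limited printed precision.

## Known limitations

* Gaussian outcome, linear time only; no autocorrelated or heteroscedastic
  level-1 residuals.
* No MR-Egger/median/mode variants; no overdispersion estimation; no
  index-event-bias correction — effects of instruments on disease incidence
  itself will bias progression MR in diagnosed-only samples.
* First-stage uncertainty in γ_k is ignored (standard two-sample practice
  with large-GWAS instruments).
* The naive and multivariate point estimates agree closely by construction
  on well-behaved data; the multivariate machinery matters for joint
  inference, not for shifting point estimates.
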