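# mrtraj

Two-sample Mendelian Randomisation (2SMR) where the outcome is the
**trajectory of disease progression**: the causal effect of an exposure on
the intercept (severity at diagnosis) and slope (rate of worsening) of a
repeatedly measured trait, estimated jointly.

Standard 2SMR regresses SNP–outcome effects on SNP–exposure effects for a
single outcome.  When the outcome is a longitudinal trait modelled with a
random-intercept/random-slope multilevel model

    y_ij = β0k + u0i + β1k·G_ik + (β2k + u1i + β3k·G_ik)·t_ij + ε_ij,

each SNP k yields *two* correlated effects — on the intercept (β̂1k) and on
the slope (β̂3k).  `mrtraj` fits one such mixed model per SNP and combines
the effect pairs in two ways:

* **naive** — two separate fixed-effect IVW meta-regressions,
  α̂ = Σ wk γk β̂k / Σ wk γk² with wk = 1/Var(β̂k);
* **multivariate** — a fixed-effects multivariate meta-regression (stacked
  GLS weighted by each SNP's full 2×2 covariance), which additionally
  estimates Cov(α̂_intercept, α̂_slope).

The two point estimates are nearly identical; the covariance from the
multivariate fit is what correct *joint* inference needs: confidence
ellipses (coverage ≈ 95% vs ≈ 90% for the naive rectangle), the
effect-over-time band α̂1 + α̂4·t with pointwise variance
v11 + 2t·v12 + t²·v22, a 2-df joint Wald test, and multivariate pooling
across cohorts.  A fully specified synthetic cohort generator
(MDS-UPDRS-III-like outcome; intercept ≈ 24, slope ≈ 2.25/yr,
random-effects covariance [[88.9, −6.0], [−6.0, 4.6]], residual variance
51.9, 97 instruments explaining 2–10% of exposure variance) and an ADEMP
harness quantify bias and coverage.  See `docs/methods.md` for the full
model, parameter tables, and design choices.

Intended users: biostatisticians and genetic epidemiologists studying
progression in longitudinal disease cohorts (Parkinson's, MS, …) with GWAS
summary statistics as instruments.

## Worked example

Simulate a scenario-1 cohort (2,000 individuals, 97 SNPs, instruments
explaining 10% of exposure variance, 7 annual visits) and run both MR
estimators:

```sh
mrtraj simulate --scenario scenario1 --r2 0.10 --n-individuals 2000 \
                --seed 7 --out demo_cohort
mrtraj mr --cohort-dir demo_cohort --out demo_mr
```

prints

```
naive: intercept +3.033 (se 0.778), slope +0.480 (se 0.188), corr +0.00
multivariate: intercept +3.035 (se 0.778), slope +0.481 (se 0.188), corr -0.36
```

The generating truth is intercept effect 2 and slope effect 0.45 (per
exposure SD); both estimates cover it (z ≈ 1.3 and 0.2 at this cohort
size).  The naive and multivariate point estimates agree to three decimals,
but only the multivariate fit reports the correlation (−0.36) between the
two estimates, inherited from the negative intercept–slope covariance of
the progression model.  `demo_mr/mr_result.json` carries the full output,
e.g. 95% CIs (1.51, 4.56) and (0.11, 0.85), and the joint Wald test
χ²(2) = 33.2, p = 6.2e-08 — strong evidence the exposure affects
progression considered jointly.  `demo_mr/band.csv` holds the
effect-over-time band for both methods; with negative covariance the naive
band is visibly too wide at every positive time.

A simulation study mirroring the harness (here deliberately tiny):

```sh
mrtraj study --scenario scenario1 --r2 0.10 --n-individuals 500 \
             --n-reps 20 --seed 1 --out demo_study
```

writes per-dimension metrics (bias, empirical SD, mean model SE, coverage),
joint coverages (rectangle / naive ellipse / multivariate ellipse) and mean
ellipse areas, plus per-replicate records and a run manifest.

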