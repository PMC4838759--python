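# Methods

## Estimand and estimator

The distribution coefficient K for an ordered blood-matrix pair (y, x) is
the expected ratio of a chemical's concentration in matrix y to matrix x
across individuals. It is estimated by least squares through the origin on
paired per-participant concentrations, K̂ = Σxy/Σx², with standard error
√[SSE/(n−1)/Σx²]. One parameter is estimated, so the residual degrees of
freedom are set to n − 1; where the convention matters the companion
with-intercept fit (slope, intercept, R²) is reported alongside.

Goodness of fit for the no-intercept model is R²ₑₛₜ = 1 − SSE/SST_c with
SST_c the corrected total sum of squares of the with-intercept model. This
statistic is bounded above by 1, can be negative for pathological fits,
and coincides with the ordinary R² when the true intercept is zero — the
regime the data are in, which is why both parameterizations give nearly
identical coefficients.

Two caveats are deliberate properties rather than bugs:

- Under the multiplicative noise model (below), residuals scale with x, so
  the homoscedastic SE understates the sampling spread of K̂ (empirically
  by ~25–35% for lognormal concentration spreads with GSD ≈ 1.4). The
  ±3·SE recovery checks in the test suite pass at ~97% rather than the
  nominal 99.7% for exactly this reason.
- Half-IDL substitutes (see below) bias slopes for heavily censored
  chemicals. Fits where more than half of either matrix's values are
  substitutes carry a `low_reliability` flag; the estimate is not altered.

## Cleaning pipeline

Fixed order, idempotent on its own output:

1. **Replicate averaging.** Each (participant, chemical, matrix) group of
   instrumental replicates (2 for plasma and whole blood, 3 for DBS) is
   collapsed to its arithmetic mean. Groups whose relative range
   (max − min)/mean is ≥ 0.10 are flagged not-accepted and excluded from
   fits. The acceptance rule is stated in terms of "varying by less than
   10%" without a defined denominator; relative range over the mean is
   this package's reading. A collapsed sample counts as non-detected only
   when every replicate fell below the IDL.
2. **Censoring substitution.** Below-IDL values are replaced by IDL/2 —
   the field's traditional simple substitution. Regression-on-order-
   statistics or likelihood-based censoring methods are intentionally out
   of scope.
3. **Detection filter.** Chemicals detected in fewer than 25% of a
   matrix's samples are dropped from that matrix's analyses; exactly 25%
   is retained ("fewer than" is strict).
4. **Modified Bland-Altman screen.** Per chemical, the per-participant
   log-ratio log(y/x) is compared with the chemical's mean log-ratio;
   deviations beyond 3 sample SDs are flagged. Log-ratios (not the
   classical differences) are used because the quantity of interest is a
   multiplicative coefficient. The slope of log-ratio on mean level
   (y + x)/2 supports the "no concentration dependence" check. The screen
   reports and flags only — deletion requires an explicit user action, so
   an audit trail survives.

Normality p-values are Lilliefors-style: the KS distance with estimated
mean/SD referred to a Monte-Carlo null of 10⁴ normal samples of the same
size (null distribution cached per n, internally seeded). Between-chemical
association uses Spearman rank correlation (product-moment correlation of
mid-ranks).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, per participant
i and chemical c:

- latent whole-blood concentration B ~ lognormal(GM, GSD);
- plasma latent = K_pb · B · exp(ε), ε ~ N(0, σ_ratio) — participant-level
  scatter of the plasma/blood ratio;
- DBS latent = (B / K_bd) · exp(δ), δ ~ N(0, σ_dbs);
- each replicate multiplies its latent value by exp(cv·z), cv = 0.03 by
  default (the replicate agreement typical of these assays). Noise is
  multiplicative throughout so concentrations stay positive.

Values below the matrix IDL are flagged and left raw; substitution is the
pipeline's job. IDLs default to the geometric midpoint of the class range
(pesticides/CHCs 5–30, PCBs 0.1–0.9, BFRs 0.1–30 ng/L in plasma/blood;
10–120, 0.8–22, 8–200 ng/L in DBS).

The **paper-like preset** parameterizes ~30 POPs from the bundled
registry: GM = the bundled cohort whole-blood median, GSD from lognormal
moment matching of the bundled whole-blood mean/SD, generating K's equal
to the bundled coefficients, and σ_ratio calibrated analytically so the
fitted SE at n = 21 matches the bundled SE:

    σ_ratio² = (SE·√(n−1)/K)² − cv²/n_rep_y − cv²/n_rep_x.

Participants carry the cohort's covariate margins (12/21 male, 16/21
white, 14/21 graduate degrees, 16/21 never-smokers; ages uniform 29–65).

What the generator does **not** emulate: between-chemical correlation
(an optional common latent factor is not parameterized by any published
value and defaults off), chromatographic interference for co-eluting
congeners, storage or extraction artifacts, and any departure from
lognormality. Passing tests therefore validate the estimators and
pipeline logic under the assumed structure; they are not evidence about
real cohorts.

Covariate effects in the cohort generator act additively on the
participant log-ratio (keeping concentrations positive); the separate
ratio-study simulator used for natural-scale regression checks applies
additive effects directly to the ratio, matching how the effect sizes are
reported. Its default residual SD of 0.4 reproduces the ~0.2 SE scale of
the reported sex coefficients at n = 21.

## Biophysical partition model

A compartment is (N, P, W) mass fractions of neutral lipid, phospholipid
and water; a chemical enters through S_w and K_ow (S_o = S_w·K_ow).
Phospholipid is treated as a fixed 70/30 water-like/octanol-like blend;
the split is hard-coded. Key algebraic facts, all property-tested:
K(a,b)·K(b,a) = 1; K depends on solubilities only through K_ow; K is
monotone in K_ow between its water-dominated and lipophilic limits; the
K_ow→∞ limit is (N_t + 0.3P_t)/(N_b + 0.3P_b), independent of water.

Whole blood defaults to N = 0.0044, P = 0.0021, W = 0.80 and liver to
N = 0.0281, P = 0.0389, W = 0.72 (published values). The plasma
composition behind the published predictions is cited but not tabulated,
so the bundled plasma composition (N = 0.0046, P = 0.0023, W = 0.95) is a
clearly labelled synthetic stand-in chosen to put plasma/whole-blood
predictions near 1.05; real analyses should supply their own via
configuration. For the lipophilic POPs handled here the predictions
cluster within <0.02 of each other near 1 — far below the experimental
1.6–2.3 — quantifying the model's known omission of protein binding and
cellular-matrix effects.

Two published worked numbers do not reproduce from their stated inputs
and are documented rather than forced: a liver/blood coefficient quoted
as 9.37 exceeds the lipophilic-limit ceiling of ≈7.91 implied by the
printed compositions (water terms can only lower it); and a quoted 67%
plasma mass fraction for K_pb = 1.58 differs from the formula value
min(1, 1.58 × 0.45) = 71%. The implementation follows the formulas.

The mass-balance bound is 1/w_p (≈1.8 at the anatomical plasma weight
fraction 0.55); the implied plasma mass fraction min(1, K_pb·w_p_eff)
uses the effective fraction 0.45 that reconciles the bound with the
experimental coefficients.

## Conversion policy

Direct pair coefficients are preferred; otherwise the path pivots through
whole blood (the most precisely measured matrix). Relative SEs propagate
first-order: se/β per leg, root-sum-square across legs. Missing PCB/PBDE
congeners may fall back to the class-average plasma/whole-blood
coefficient; pesticides/CHCs and TBBPa require compound-specific values
(their coefficients vary too much across compounds) and the fallback must
be forced explicitly. Whole-blood/DBS coefficients statistically
consistent with 1 (two-sided t on (β−1)/se, n−1 df, α = 0.05) default to
exactly 1, flagged, with `prefer_fitted=True` as the override. Half-IDL
substitutes convert like any value but keep their flag; their
interpretation after conversion is the user's call.

## Problem sizes and numerical choices

Monte-Carlo checks use 500 cohort replications for coefficient recovery,
200 for covariate-effect recovery, and 1000 for the null type-I-error
check — sizes at which binomial error on the checked proportions is well
inside the asserted margins. The Lilliefors null uses 10⁴ replications.
All randomness flows through numpy Generators seeded explicitly;
identical seeds give byte-identical cohorts. Degenerate inputs are
defined errors, not silent results: all-zero regressors, empty
compartments, sub-3-pair fits, out-of-range mass fractions and
probabilities all raise typed exceptions, and all-zero replicate groups
are flagged degenerate rather than averaged.

## Known limitations

- Serum is not modelled (never measured; no serum coefficient exists).
- Lipid-adjusted (ng/g-lipid) reporting is out of scope.
- The estimator is deliberately the field's standard through-origin OLS;
  Deming/errors-in-variables or mixed-effects alternatives would handle
  the x-side measurement error more gracefully but are not implemented.
- Class-average fallbacks inherit the registry cohort's demographics;
  coefficients may differ in populations with very different hematocrit.
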