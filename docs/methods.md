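# Methods

## Causal estimands

The exposure `R` (1 = reference group, 0 = comparison group) is a
non-manipulable group label; no intervention on it is defined, so the
causal content of the analysis lives in hypothetical interventions on
the mediator, the microbiome composition `M` (a point on the
J-simplex). Writing `Y_{M_x(r)}` for the outcome that would obtain if
the composition were drawn from group `r`'s mediator distribution at
covariates `x`, the estimands are

- MDM = E[ E[Y_{M_x(1)} | R=1, x] − E[Y_{M_x(0)} | R=1, x] ] — the part
  of the disparity that equalizing microbiome profiles would remove;
- RDM = E[ E[Y_{M_x(0)} | R=1, x] − E[Y_{M_x(0)} | R=0, x] ] — what
  would remain;
- ODM = MDM + RDM.

Identification needs `Y ⫫ R | X` and `Y ⫫ M | R, X`: all confounding of
the group–outcome and mediator–outcome relations is captured by the
measured covariates. These are assumptions, not testable properties;
the matching step reduces, but cannot rule out, violations of the
first.

## Working models and closed forms

The outcome follows a Gaussian linear log-contrast model with
exposure × taxon interactions and sum-to-zero constraints on both taxon
coefficient vectors; the constraints make the fit invariant to the
compositional scale, so results do not depend on sequencing depth
conventions. The mediator follows a Dirichlet regression with a log
link on each concentration. Under these models
`E[log M_j | r, x] = ψ(γ_j(r, x)) − ψ(Σ_m γ_m(r, x))` with ψ the
digamma function, which gives the closed forms for MDM_j, RDM and ODM
used throughout (verified against brute-force Monte-Carlo simulation
in the test suite). The decomposition identity ODM = MDM + RDM and
MDM = Σ_j MDM_j holds exactly — it is algebra, not an approximation —
and is asserted to 1e-10.

The covariate expectation is taken over the empirical covariate vectors
of the reference-group (R = 1) samples in the analyzed data, matching
the outer expectation of the estimand. Pooled-sample or fixed covariate
sets are available; after matching, the choice is nearly immaterial
because the covariate distributions coincide by construction.

## Estimation

**Mediator.** Maximum likelihood, by default a damped Newton iteration
with the analytic gradient (digamma) and Hessian (trigamma), started
from a method-of-moments common-concentration fit; quasi-Newton
(L-BFGS) is the fallback and remains available as `method="lbfgs"`.
Convergence: gradient max-norm < 1e-6 or relative log-likelihood change
< 1e-9. Standard errors come from the observed information.

**Outcome.** Unpenalized fits solve least squares in an orthonormal
basis of the sum-to-zero subspace, so the constraints hold to machine
precision by construction. The penalized selection fit minimizes

    ½·RSS/n + λ₁(‖α_M‖₁ + ‖α_C‖₁) + λ₂ Σ_j ‖(α_Mj, α_Cj, β̂_Rj)‖₂

with β̂_Rj fixed from the mediator fit. With β̂_Rj ≠ 0 the group term
is smooth, so exact sparsity comes from the L1 term while the group
term shrinks whole mediation pathways jointly — mirroring the product
structure of MDM_j, which vanishes unless both path legs are nonzero.
The solver is a monotone FISTA (compiled with numba): the proximal step
for L1-plus-sum-to-zero is solved *exactly* through its piecewise-linear
scalar dual, so iterates carry exact zeros and exactly centered blocks,
and candidates that would raise the objective are rejected, making the
objective sequence non-increasing by construction. |β̂_Rj| is floored
at 1e-8 to keep the group term differentiable.

**Penalty tuning.** Candidates are a 6-point geometric path of λ₁ from
0.6 to 0.08 of the data-driven null-gradient bound, with λ₂ = λ₁/2
(the usual sparse-group tying); the pair is chosen by extended BIC,
`n·log(RSS/n) + df·(log n + 2·log 2J)`. Plain BIC over-selects here —
log-contrast columns are strongly correlated by compositionality — and
in pre-runs on sparse ground truth (3 active of 20 taxa, n = 400) the
extended criterion reached sensitivity 0.99 at specificity 0.84 where
plain BIC gave 0.63 specificity. `bic`, `aic` and explicit grids remain
configurable.

**Splitting.** Point estimates and uncertainty come from 50 random
half-splits stratified by exposure: half A selects taxa, half B refits
both models unpenalized on the selected subcomposition (the
subcomposition of a Dirichlet vector is Dirichlet with the same
concentrations, and the sum-to-zero constraint makes the log-contrast
fit invariant to the renormalization, so the restricted models remain
correctly specified) and evaluates the formulas; unselected taxa
contribute MDM_j = 0. The reported SE is the standard deviation of the
per-split estimates — the splits share data, so the spread itself, not
spread/√reps, is the honest uncertainty — and the 95% CI is the normal
approximation mean ± 1.96·SE (percentile CIs by flag). Fewer than two
selected taxa collapse the refit to `Y ~ 1 + X + R` (a single selected
taxon cannot carry a sum-to-zero contrast).

**Testing.** OMD = M̂DM (two-sided) and CMD = Σ_j M̂DM_j² (one-sided,
detects cancelling per-taxon effects) are referred to their permutation
distributions: exposure labels are permuted across subjects — breaking
both the R→M and R→Y paths, a valid null for "no mediated disparity" —
and the entire split procedure is rerun per permutation. Add-one
p-values bound the minimum at 1/(n_perm+1). The observed statistic is
computed with the same number of inner split repetitions as the
permuted ones (default 5) so that observed and null statistics are
exchangeable under H₀; raising inner repetitions to 50 is a flag, and
in pre-runs the null distribution was insensitive to the inner-rep
count while costing 10× more.

**Matching.** P(R=1|X) by unpenalized logistic regression (ridge
fallback on separation), greedy 1:1 nearest-neighbor matching without
replacement on the logit of the score, hardest-first order, caliper
0.2 × SD of the logit by default, exact-matching strata supported.
Balance is summarized by the arithmetic mean of per-covariate absolute
standardized mean differences (binary covariates use binomial
variances); below 0.1 is treated as balanced. The seed only breaks
exact distance ties.

## Preprocessing defaults

Taxa are kept when nonzero in ≥ 20% of samples and mean relative
abundance ≥ 1e-4 (both configurable and logged; species counts in any
particular cohort depend on these choices). Zeros are replaced by half
the sample's smallest nonzero abundance followed by row renormalization
(`half_min`); a multiplicative variant that preserves nonzero ratios is
available. Both guarantee strictly positive rows summing to one, which
log(M) and the Dirichlet likelihood require.

## Synthetic data

The generator draws covariates standard normal (binary columns
optional), assigns groups either by balanced randomization or by a
logistic confounding model on X, draws compositions from the Dirichlet
mediator model and outcomes from the log-contrast model with Gaussian
noise — exactly the laws the estimators assume. Each dataset carries a
truth record with the analytic MDM/RDM/ODM at the generating
parameters, evaluated over the realized reference-group covariates, so
recovery is checked against a known target. Presets:

- `null_no_mediation` — exposure shifts taxa (β_R ≠ 0) but taxa do not
  affect the outcome; true MDM = 0 (type-I error studies).
- `mediation_only` — α_R = 0 with three mediating taxa; with no direct
  effect the manipulable share is necessarily dominant (~93%).
- `direct_only` — β_R = 0, α_C = 0; true MDM = 0 and RDM = α_R exactly.
- `mixed` — mediation plus a direct effect sized so the manipulable
  share sits near 25%, inside the 20–35% band reported for real
  cohorts; this is the demonstration scenario.
- `confounded` — covariates drive group membership (logistic
  coefficients 0.8 on the continuous and 1.0 on the binary covariate),
  for matching studies.

Baseline concentrations are geometric from 2.0 down to 0.4 (total ≈ 10
for J = 10), giving the uneven, overdispersed compositions typical of
small communities; exposure effects on the three active taxa are
(0.8, −0.8, 0.6) on the log-concentration scale and outcome effects
(α_M + α_C) are (1.4, −0.7, −0.7), with noise SD 1 on the outcome.
Because data are generated from the working models, passing recovery
tests demonstrates correctness of the machinery, not robustness to
model misspecification (zero inflation, overdispersion beyond
Dirichlet, nonlinear outcome effects) — real-data use still rests on
the modelling assumptions.

## Problem sizes and numerical choices

Simulation studies in the tests use: recovery, 20 studies of n = 600
(10 taxa, 3 active, 50 splits); type-I error, 100 null studies of
n = 300 (8 taxa) with 199 permutations × 5 inner splits; balance, 50
confounded studies of n = 400. These sizes make the full suite run in
minutes on one core while leaving Monte-Carlo error well inside the
asserted bands. Coefficients with |value| < 1e-10 after optimization
are treated as exact zeros; rank-deficient unpenalized designs receive
a 1e-10 ridge jitter; Dirichlet linear predictors are capped at ±500
before exponentiation, with an explicit overflow error at the public
interface. Degenerate splits (an exposure level missing from a half)
are redrawn; split repetitions that fail to fit are dropped and at
least 80% must succeed.

## Known limitations

Continuous outcomes only; binary exposure only; no sensitivity analysis
for unmeasured confounding; no zero-inflated or count-level
(multinomial) mediator model; selection inference is conditional on the
penalty family and tuning criterion; the permutation scheme tests the
global null of no mediated disparity, not per-taxon hypotheses.
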