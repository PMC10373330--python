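# micromediate

How much of a between-group difference in a health outcome runs through
the gut microbiome — and would disappear if microbiome profiles were
equalized between the groups?

`micromediate` answers this for *non-manipulable* exposures such as
ethnicity or region, where no intervention on the exposure itself is
conceivable and the causal question must be posed through the mediator.
Given a samples × taxa relative-abundance table, a binary group label
`R` (1 = reference group), a continuous outcome `Y` (e.g. BMI) and
covariates `X`, it decomposes the overall disparity measure (ODM) into
a **manipulable** part carried by microbiome composition (MDM, with
per-taxon contributions MDM<sub>j</sub>) and a **residual** part (RDM),
with regularized taxon selection, split-based standard errors, and
permutation tests. It is written for microbiome epidemiologists and
biostatisticians analyzing observational cohorts.

## Model

Outcome — a linear log-contrast regression with exposure × taxon
interactions:

```
Y_i = α₀ + α_X' X_i + α_R R_i + α_M' log(M_i) + α_C' log(M_i) R_i + ε_i,
      Σ_j α_Mj = 0,  Σ_j α_Cj = 0,  ε_i ~ N(0, σ²)
```

Mediator — Dirichlet regression of the composition with a log link on
each concentration parameter:

```
M_i | (R_i, X_i) ~ Dirichlet(γ₁(R_i, X_i), …, γ_J(R_i, X_i)),
log γ_j(R, X) = β₀j + β_Rj R + β_Xj' X
```

Under these models the disparity measures have closed forms through the
digamma function ψ (since E[log M_j | r, x] = ψ(γ_j) − ψ(Σ_m γ_m)):

```
MDM_j = (α_Mj + α_Cj) · { E[log M_j | R=1, x] − E[log M_j | R=0, x] }
MDM   = Σ_j MDM_j
RDM   = α_R + Σ_j α_Cj · E[log M_j | R=0, x]
ODM   = MDM + RDM
```

MDM_j is nonzero only when both the taxon's effect on the outcome and
the exposure's effect on the taxon are nonzero — the defining product
structure of a mediated path.

Estimation follows a two-step, split-based procedure: one random half
of the sample (stratified by exposure) selects taxa by minimizing

```
½·RSS/n + λ₁(‖α_M‖₁ + ‖α_C‖₁) + λ₂ Σ_j ‖(α_Mj, α_Cj, β̂_Rj)‖₂
```

under the sum-to-zero constraints (β̂_Rj fixed from the mediator fit,
so weakly mediating taxa are shrunk jointly); the other half refits
both models unpenalized on the selected taxa and evaluates the
formulas. Fifty repetitions give means, SEs and 95% CIs. Significance
of OMD = M̂DM and CMD = Σ_j M̂DM_j² comes from permuting the exposure
labels and rerunning the whole procedure. Because group membership is
not randomized, propensity-score matching (1:1 nearest neighbor on the
logit, optional exact strata and caliper) with standardized-mean-
difference diagnostics is built in as the confounding-control step.

## Worked example

Generate a synthetic cohort from the built-in mixed scenario (3
mediating taxa of 10, one confounder, ~25% of the disparity mediated)
and run the full pipeline:

```sh
$ micromediate synth --preset mixed --n 150 --taxa 10 --seed 7 --out demo
true MDM = 1.6833, RDM = 4.9892, ODM = 6.6725

$ micromediate run --taxa demo/taxa.tsv --metadata demo/metadata.tsv \
    --exposure exposure --outcome outcome --covariates x1 \
    --n-reps 50 --n-perm 99 --inner-reps 5 --seed 1 --out demo/result
assembled 300 samples x 10 taxa (0 unmatched ids dropped)
matched 134 pairs; overall SMD 0.018 -> 0.003
10 taxa after filtering
ODM = 6.6756  MDM = 1.8258 (SE 0.2282)  RDM = 4.8499
percent of disparity manipulable through the microbiome: 27.35%
OMD p = 0.01   CMD p = 0.01 (99 permutations)
```

The estimated decomposition (ODM 6.68 = MDM 1.83 + RDM 4.85) recovers
the generating truth (6.67 = 1.68 + 4.99) within the across-split SE,
the manipulable share lands near the true 25%, and both permutation
tests reject at their floor (1/(99+1) = 0.01): the mediated signal is
detected at the community and taxon level. `demo/result.tsv` lists the
per-taxon MDM_j with SEs, CIs and selection frequencies — the three
generating taxa are selected in every split; `demo/result.json` holds
the summary, and `demo/result.match.json` the matching report.

The same analysis is available as a scikit-learn-style estimator
(`MicrobiomeMediationDisparity(...).fit(X, y)` with columns
`[R, X, M]`), with `DirichletRegression`, `LogContrastRegression` and
`PropensityMatcher` usable on their own.

Real-data inputs in TSV/CSV (or BIOM 2.1) work the same way via
`--reference-label` to declare which exposure level is coded R = 1;
see `micromediate run --help`.

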