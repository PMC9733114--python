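# Methods

This note records the statistical choices behind `equiprev`: the estimators,
the inequality measures and their uncertainty intervals, what the synthetic
survey generator does and does not emulate, and the numerical conventions.

## Design-based estimation

Records carry a stratum, a cluster (primary sampling unit, PSU), a positive
sampling weight and a binary outcome. The subgroup and overall prevalences
are Hájek ratio estimators,

    p̂ = Σ wᵢ yᵢ / Σ wᵢ   (reported ×100, percent scale),

with subgroup estimates treated as *domain* estimates: every PSU in the
design contributes to the variance, including PSUs with no members of the
domain.

**Variance.** The SE comes from the stratified between-PSU Taylor
linearization under the with-replacement approximation: with linearized
scores `uᵢ = wᵢ(yᵢ − p̂)/Ŵ` summed to PSU totals `z_hc`,

    v(p̂) = Σ_h n_h/(n_h − 1) Σ_c (z_hc − z̄_h)².

No finite-population correction is applied — the standard convention for
MICS/DHS-type designs, where first-stage sampling fractions are small. It
is mildly conservative when the synthetic sampler's fractions are larger.
Strata with a single PSU contribute zero variance under the default
`certainty` policy (with a warning); `error` and `collapse` (pool all
single-PSU strata) policies are available.

**Confidence intervals** use a normal interval on logit(p) with the
delta-method SE, back-transformed. This keeps intervals inside (0, 100)
and asymmetric in the way published survey tables are. At a boundary
estimate (0 or 100) an exact binomial one-sided bound on the unweighted
count is substituted. Critical values are normal rather than t: PSU counts
in the target designs are large, and the tests verify 93–97% empirical
coverage at the sizes the package simulates. The construction is invertible,
which the reproduction pipeline uses to recover percent-scale SEs from
published CIs; on the packaged tables this reproduces the published D and R
uncertainty intervals to the printed decimal almost everywhere (e.g.
regional D 2011: computed [30.6, 70.4] vs published [30.7, 70.4]).

## Inequality summary measures

Definitions are in the README. Conventions that needed a decision:

- **Reference group.** For ordered/binary dimensions the advantaged extreme
  is fixed by the declared subgroup order, whatever the estimates. For
  non-ordered dimensions (region) the extremes are data-driven; for a
  favourable indicator y_ref is the *best-performing* subgroup. This is the
  convention consistent with PAR's reading as the attainable population
  gain, and with the published regional PAR values the package reproduces
  (29.7 = 62.3 − 32.6 in 2011; 25.8 = 75.5 − 49.7 in 2017). Ties are broken
  by label sort with a warning. An adverse-indicator mode mirrors the rules
  (best = lowest; PAR truncated from above at zero).
- **PAR truncation.** Reported PAR is `max(0, y_ref − μ)`: a reference at
  or below the overall average means no inequality in the attributable
  sense. The uncertainty interval is a normal interval centred on the
  *reported* estimate with SE `√(se_ref² + se_μ²)` and unclipped bounds, so
  a truncated PAR of 0 carries a symmetric interval — the presentation used
  in published equity tables (e.g. 0 with bounds ∓6.4).
- **Covariance.** The delta variance of PAR ignores cov(y_ref, μ) even
  though the reference subgroup is part of the overall mean. The cluster
  bootstrap (`bootstrap_measures`, percentile intervals over stratified
  Rao–Wu cluster resamples) is the covariance-honest alternative and is
  how the delta intervals are checked.
- **Simple vs complex.** D and R use subgroup estimates alone; PAR and PAF
  additionally use the population-weighted average μ, which is how the
  "simple unweighted" vs "complex weighted" distinction enters.
- **Reporting.** Estimates are carried unrounded; reports round to one
  decimal, half away from zero. Comparisons against published values are
  made after identical rounding. μ for the packaged reproduction is taken
  from the published overall prevalences (32.6, 49.7) — microdata are out
  of scope — with se_μ treated as 0 there; point estimates are unaffected.

Two packaged cells are known not to reproduce at the printed decimal from
rounded published inputs (2011 regional PAF 91.3 vs 91.1; 2017 residence D
−26.1 vs −26.0). These are rounding-provenance artefacts of starting from
the published (rounded) subgroup estimates; the reproduction flags them
with notes instead of failing or hiding them.

## Synthetic MICS-like surveys

The generator builds a *frame* — regions × urban/rural strata, each with a
configurable number of EAs whose household counts vary uniformly around a
mean — and then samples it in two stages: systematic PPS on EA household
counts (with certainty selection for oversized units and a random start on
the cumulated-size scale), then SRS of households within each selected EA.
Weights are inverse inclusion probabilities, so the design is approximately
self-weighting within strata. All eligible women (one per household with
probability `eligible_rate`) in a sampled household are interviewed.

Outcomes follow a logistic model: region baseline + additive log-odds
effects of residence (centred on the region's urban share), wealth quintile
and education, plus an EA-level normal intercept with variance
`σ² = icc·π²/3/(1 − icc)` — the latent-threshold mapping from the target
intra-cluster correlation. Wealth quintiles are derived the way survey
programmes derive them: the first principal component of the standardized
binary asset matrix, sign-aligned so higher score means more assets, cut at
the 20/40/60/80th percentiles. Education is an ordinal cut of a
wealth/urban-driven latent score.

**Truth and the census identity.** Outcomes are realized once, when the
frame is built (a pure function of the config, including its seed).
`true_summaries` therefore reports *frame-realized* subgroup prevalences
and the measures computed from them by the same closed-form rules the
estimators use: a census sample reproduces the truth exactly, and repeated
subsamples of one frame have a fixed estimand. The model-expected
prevalences (average model probabilities, free of outcome-level binomial
noise) are exposed alongside as `model_prevalences`/`model_measures`; they
are the quantities that sit exactly at the no-inequality values when all
covariate effects are zero.

**Default scenario.** Ten regions with baselines, urban shares and
wealth-shifts arranged to mimic the 2017 Ghana pattern (high ITN use in the
northern regions and Volta, low in the heavily urban capital region; use
declining with wealth and education and lower in urban areas); 40 EAs per
stratum of ~100 households in the frame; a sample of 5 EAs per stratum × 36
households per EA at eligibility 0.26, i.e. ~930 respondents — the scale of
the 2017 analytic sample. Default ICC 0.06 (a design effect of ≈1.5 at ~9
women per cluster, typical for this kind of indicator; source surveys
publish no ICC for it, so this is a modelling choice, not an empirical
claim). The validation runs use 500 replicate surveys at this size, and a
single-region, 2-stratum/30-PSU design for the bootstrap-oracle checks;
these sizes keep every check a desk computation while leaving Monte-Carlo
error well below the tolerances tested.

**What the generator does not emulate:** nonresponse and calibration or
poststratification of weights, household listing operations, within-region
geography, seasonal or campaign effects, and reporting bias in the outcome.
Passing recovery tests therefore show the estimators are correct for the
stated design, not that real MICS estimates are free of those additional
error sources.

## Numerical conventions and degenerate inputs

- Estimates on the 0–100 percent scale everywhere; proportions only inside
  variance formulas.
- CSV interchange: comma-separated, UTF-8, `.` decimal, one header row;
  missing optional fields are empty cells, never sentinel numbers; numeric
  output at full float precision so write∘read is the identity.
- Validation is total: malformed cells and invariant violations raise with
  the offending row named; unknown dimensions are dropped with an explicit
  warning; empty subgroups are omitted with a warning.
- A subgroup with constant outcome has SE 0 and a point interval (or exact
  binomial bound at the boundary). A zero denominator makes R an error, and
  μ = 0 makes PAF an error.
- Per-dimension failures in batch computation are isolated: other
  dimensions still compute, and failures are returned alongside results.

## Known limitations

- The uncertainty-interval constructions for the published tables are this
  package's own (delta/bootstrap); the tool used for the original analysis
  does not document its internals, so only point estimates are claimed to
  reproduce, with the interval agreement shown above as corroboration.
- The PAR delta interval's zero-covariance approximation slightly inflates
  its width when the reference subgroup is a large share of the population;
  use the bootstrap for honest intervals in that case.
- Jackknife/BRR replicate weights, finite-population corrections and
  poststratification are out of scope, as are regression-based summary
  measures (slope/relative index of inequality, concentration index).
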