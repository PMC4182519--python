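# Methods

This package implements a multidimensional poverty analysis for stratified,
clustered household surveys: the Alkire–Foster (AF) dual-cutoff adjusted
headcount over 11 weighted deprivation indicators, its decompositions and
cut-off robustness, design-based variance estimation, enumeration-area (EA)
poverty surfaces by ordinary kriging, and an asset-based latent wealth index.
A calibrated synthetic survey generator supplies data with the structure the
analysis assumes, so every stage is testable end to end.

## The Alkire–Foster adjusted headcount

Each household i has a binary deprivation vector g⁰ᵢ over 11 indicators in
three dimensions. Weights are exact rationals summing to one — education
2 × 1/6, health 1/6 + 1/12 + 1/12, living standard 6 × 1/18 — so each
dimension carries 1/3 and every attainable weighted score cᵢ = Σⱼ wⱼ g⁰ᵢⱼ is a
multiple of 1/36. A household is poor when cᵢ ≥ k (inclusive rule, default
k = 1/3). Scores of the non-poor are censored to zero, and with sampling
weights sᵢ:

- headcount H = Σ sᵢ·poorᵢ / Σ sᵢ,
- intensity A = Σ sᵢ·cᵢ·poorᵢ / Σ sᵢ·poorᵢ (defined as 0 when H = 0),
- adjusted headcount M0 = Σ sᵢ·cᵢ(k) / Σ sᵢ = H·A = Σⱼ wⱼ·CHⱼ,

where CHⱼ is the censored headcount of indicator j. Indicator contributions
are wⱼCHⱼ/M0; M0 is additively decomposable, so population-share-weighted
subgroup values recombine exactly to the pooled value. Scores and the
cut-off are compared in integer arithmetic over the weight LCD, so
households sitting exactly at c = k (an attainable score under these
weights, which makes the inclusive/exclusive choice consequential) never
flip with floating-point noise. The inclusive rule is the default; an
exclusive variant is exposed on `AFParams`.

The robustness grid of cut-offs spans 1/9 to 2/3 of the weighted score:
steps of 2/36 below one quarter, steps of 1/36 from one quarter to two
thirds — 19 cut-offs, the grid conventionally tabulated for this indicator
set. (The full attainable-subset-sum set in that interval has 21 values;
`attainable_scores()` computes it for any weight vector.)

## Indicator rules and missing data

The 11 rules are documented in `mdpoverty.deprivation`. Choices where the
rule wording is ambiguous:

- **Child enrollment** applies to school-aged children (7–14); households
  with no school-aged child are non-deprived (the standard convention for
  non-applicable indicators).
- **Water**: deprived if the source is a river OR the source is more than
  30 minutes away travelled on foot; a motorized trip over 30 minutes is
  not deprived.
- **Housing material** tests the roof (grass/cane/leaves/straw).
- The third health indicator is defined by recent child acute illness
  (fever, diarrhea, difficulty breathing in the last 30 days).

Missing required fields raise an error naming the field; nothing is
imputed. The analysis is meant to run on complete interviews.

## Synthetic survey generator

The generator emulates a two-stage provincial cluster sample: 259 EAs
(default) in four district strips of a planar 100 × 100 region, 15
households per EA, 96 % of EAs rural. Each indicator deprivation follows a
probit threshold model: deprivedᵢⱼ iff z_e(i) + δ·urbanᵢ + εᵢⱼ < tⱼ, with
εᵢⱼ ~ N(0,1) iid, z_e a zero-mean Gaussian EA effect with exponential
covariance sill·exp(−d/range) (defaults sill 0.3, range 10 — moderate
within-EA clustering on the latent scale, ICC ≈ 0.23), and δ an urban
latent advantage (default 0.75) making urban households systematically less
deprived, as in predominantly rural provinces. The shared EA effect
correlates households within an EA and indicators within a household, and
gives the kriging stage a real spatial signal.

Thresholds are calibrated to the 11 target marginals (defaults: the
published provincial deprivation rates, 14.7 % … 43.2 %) in one of two
modes:

- `"sample"` (default): tⱼ solves the realized-mixture equation
  mean(Φ(tⱼ − zᵢ)) = pⱼ, so observed rates match targets up to
  household-level binomial noise — the generator's purpose is a survey
  whose marginals match the published table.
- `"population"`: tⱼ is fixed from the unconditional mixture, so marginals
  match in expectation over the spatial field and the superpopulation
  headcount is analytically available: conditional on z the indicators are
  independent Bernoulli, the integer-score distribution follows by dynamic
  programming, and z integrates out by Gauss–Hermite quadrature
  (`expected_headcount`). This mode provides the known estimand for
  variance-coverage studies.

Raw survey fields (literacy/numeracy scores, HDDS, water access, asset
flags…) are synthesized at the rule boundary with jitter inside the legal
range; downstream analysis consumes only the binary outcome. Monetary
income is zero with calibrated probability 0.49, tied to the same latent
(no-income households cluster with the deprived), lognormal otherwise
(median ≈ 400 MZN among earners, σ = 1.25). A wealth latent
θ = (z + ε)/√(1+sill) drives 37 binary asset items through a one-factor
probit with loadings U(0.6, 1.6) and intercepts N(−0.4, 0.9). Sampling
probabilities come from PPS EA selection on a synthetic size measure with
(approximately) equal-probability households within EA; strata are
district × urban/rural. All randomness flows from one seeded generator, so
output is bit-reproducible.

What the generator does *not* emulate: real joint dependence between
indicators beyond the single shared latent (field data show richer
cross-indicator structure, so the synthetic headcount at k = 1/3 — about
0.53 — need not equal a field value), interviewer and measurement error,
household non-response, the quadrant-walk household selection, or
anthropometry. Passing tests therefore demonstrate correctness of the
estimators under a known data-generating process, not agreement with any
particular field survey.

## Design-based variance

Point estimates are inverse-probability-weighted ratios. Variances use
Taylor linearization with the with-replacement PSU approximation (no
finite-population correction): the linearized residual
uᵢ = sᵢ(yᵢ − R xᵢ)/X̂ is totalled per EA and contrasted within strata with
the nₕ/(nₕ−1) factor. Intervals use the normal reference — adequate at the
PSU counts these surveys run at (hundreds of EAs). A stratum with a single
PSU is treated as a certainty unit (zero variance contribution, logged);
`lonely="collapse"` pools lonely strata instead. The default stratification
is district × urbanicity. Intensity A is a domain ratio (censored score
over poor indicator) and gets the same linearization.

A coverage simulation (500 replicates of 60 EAs × 6 households,
population-calibrated thresholds, spatial range 0.5) checks the 95 %
interval for H against the analytic estimand; coverage lands at 93–95 %.
The short range makes EA effects effectively independent between PSUs —
the setting the with-replacement approximation assumes — while within-EA
clustering, the phenomenon the estimator exists to absorb, is untouched.
Under a long spatial range the between-PSU independence assumption is
violated and some undercoverage is expected; that is a known property of
design-based variance under spatial correlation, not an implementation
artifact.

## Ordinary kriging of EA poverty

The adjusted headcount aggregates to EA level as the weighted mean censored
score within EA (these recombine exactly to the overall M0). The empirical
semivariogram bins half squared differences; a parametric model
(exponential default; spherical, gaussian selectable) is fitted by weighted
least squares with Cressie/gstat weights Nⱼ/hⱼ², which anchor the fit at
short lags where range information lives — with pair-count weights alone
the fitted range inflates noticeably on simulated fields. Ordinary kriging
solves the standard system with the unbiasedness constraint per grid node
(one factorization of the (n+1)² matrix, all nodes solved together);
weights sum to one to ~1e-15, and a zero nugget reproduces data values
exactly. A singular system gets one ridge-jitter (1e-10) retry. Kriging is
run per district by default (100 × 100 grid over the district bounding
box). Raw predictions may leave [0,1]; a clamped copy is kept alongside for
display and the kriging variance is floored at zero. Distances are planar
Euclidean — the mapped districts are small enough that a planar
approximation is standard.

## Latent wealth index

For dichotomous asset items the hierarchical ordered-probit wealth
construction reduces to the one-factor binary-probit latent-trait model
(two-parameter normal ogive): θ ~ N(0,1), P(own item m) = Φ(aₘ + bₘθ). We
implement that reduction directly — the likelihood is identical for binary
items and far simpler to estimate and test. Estimation is marginal maximum
likelihood via EM over a 21-node Gauss–Hermite grid. Because all households
share the same θ grid, the M-step reduces to 2-parameter probit fits on
posterior-weighted success/failure counts aggregated to the nodes
(Fisher scoring on a concave likelihood), so cost is independent of sample
size once the E-step matmuls are done. The marginal log-likelihood is
non-decreasing across iterations; convergence is a log-likelihood change
below 1e-7 (cap 500 sweeps, non-convergence flagged). Identification: the
latent is anchored by the standard-normal prior, and orientation is fixed
by requiring a positive loading sum (owning items indicates higher wealth).
Items owned by everyone or no one are dropped with a warning. Probit
indices are clipped at ±8 for numerical stability.

Household scores are expected-a-posteriori latent values, min-max rescaled
to [0,1] over the sample — the unit-interval scale wealth indices are
usually reported on. The lowest-quintile flag uses the survey-weighted 0.2
quantile (smallest value whose cumulative normalized weight reaches q);
ties at the boundary are all flagged. The $1.25/day comparator converts
monthly income at 30.44 days/month and 30 MZN/USD (both configurable), per
capita by household size.

## Problem sizes and tolerances

The test suite and acceptance script use sizes chosen to make Monte-Carlo
noise negligible relative to the checked tolerances while keeping runs
fast: calibration checks at n = 3000 households (200 EAs × 15), engine vs
brute-force enumeration on 100 random 200 × 11 matrices (agreement to
1e-12), CI coverage over 500 replicates of n = 360, variogram recovery on
10 replicates of 500-point fields (30 % band — the honest reproducibility
of variogram parameters from a single realization of that size), and
wealth recovery at n = 2000 × 37 items (loading correlation ≥ 0.9, score
rank correlation ≥ 0.85). Algebraic identities (M0 = H·A = mean censored
score = Σ wⱼCHⱼ, subgroup recombination, contribution sums) are checked to
1e-12 on random inputs.

## Known limitations

- Variance estimation offers Taylor linearization only; replicate-weight
  methods (BRR, jackknife) are out of scope.
- Kriging is isotropic and ordinary; no anisotropy, universal kriging, or
  cartographic rendering.
- The AF family is implemented for M0 only (binary deprivations); the
  gap-based members M1/M2 require cardinal shortfalls.
- The wealth model is single-factor with positive orientation; multi-factor
  structures are not supported.
- The generator's literacy/numeracy/HDDS scales are free integer ranges at
  the rule boundary; within-category detail is cosmetic by design.
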