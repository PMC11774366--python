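# Methods

## Scope and design

The package quantifies how the choice of areal aggregation scale affects
Bayesian small-area inference when disease counts are sparse. Its five
modules mirror the stages of such a study: `geography` (nested hierarchy,
contiguity, cross-level transfer), `standardisation` (expected counts and
SIRs), `bym` (the spatial model and its sampler), `diagnostics` (Moran's I,
residuals, Geweke), `synthetic` (scenario generation) and `pipeline`/`cli`
(orchestration and outputs).

## Geography and cross-level transfer

Hierarchies are strictly nested: each fine area belongs to exactly one
parent, and coarser populations are exact sums over children. Transfers go
through correspondence matrices whose rows sum to one. Aggregation places
unit weight on the ancestor, so totals are conserved exactly;
disaggregation distributes by descendant total-population share, which
makes fine-level counts fractional. Fractional counts are kept by default —
they are the natural product of population-share disaggregation — with an
opt-in multinomial mode that allocates each source area's integer count at
random with the row shares when integer counts are required end to end.

Contiguity from polygons uses queen adjacency (a shared boundary point
suffices), the common convention for Australian statistical geographies;
rook is available via a flag. Index scores (deprivation) are not masses:
they aggregate as population-weighted means and disaggregate by copying the
ancestor's value. Quintiles are population-weighted — areas are sorted by
score and cut at cumulative-population fractions 0.2/0.4/0.6/0.8 — so each
quintile holds about 20% of people, not 20% of areas. Levels with fewer
than five areas necessarily leave some quintiles empty; the package warns
and proceeds, since the coarsest level of the default hierarchy has only
four areas. Zero-population areas are dropped before analysis at every
level.

## Indirect standardisation

`E_i = sum_k y_k pop_ik / pop_k` with K = 18 five-year age strata by
default (0–4 … 85+, the convention for Australian cancer rates; K is
configurable). Because E is linear in the age-stratified populations, it is
computed once at the finest level and aggregated, which is exactly
equivalent to recomputing it at any coarser level of a nested hierarchy and
guarantees cross-level consistency. Areas with E = 0 get an undefined
(missing) SIR rather than 0 or infinity, and are excluded from model fits.

## The BYM model and sampler

Counts follow `Y_i ~ Poisson(E_i exp(alpha + x_i' beta + u_i + v_i))` with
an intrinsic CAR prior on `u` (conditional-variance parameterisation:
`sigma_u^2` is the variance scale of the full conditional, not a marginal
variance), iid `N(0, sigma_v^2)` on `v`, `N(0, 10^6)` priors on `alpha` and
each quintile coefficient, and Inverse-Gamma(1, 0.01) hyperpriors on both
variances. Quintile 1 is absorbed into the intercept; `beta` indexes
quintiles 2–5.

The sampler is a single-chain Metropolis-within-Gibbs kernel (numba-jitted
for speed):

- single-site Gaussian random-walk updates for each `u_i` (CAR conditional
  prior × Poisson likelihood) and each `v_i`;
- per-component mean-centring of `u` after every sweep — the intrinsic CAR
  is improper and otherwise confounded with the intercept; singleton
  components (isolated areas) are thereby pinned at zero, which keeps the
  variance update's rank correction `(n − c)` exact;
- scalar random-walk updates for `alpha` and each `beta_j` (each `beta_j`
  touches only its quintile's areas, so the likelihood delta is local);
- conjugate draws `sigma_v^2 ~ IG(a + n/2, b + Σv²/2)` and
  `sigma_u^2 ~ IG(a + (n−c)/2, b + Σ_{i<j} w_ij (u_i−u_j)²/2)`.

Proposal scales adapt multiplicatively every 100 iterations during burn-in
towards 40–50% acceptance (the efficient band for univariate random-walk
updates) and are frozen afterwards, so the post-burn-in kernel is a fixed
Markov transition. All randomness flows through one generator seeded at
entry: identical inputs and seed give bit-identical chains.

Chain defaults are desk-scale — 60,000 iterations, 10,000 burn-in, thinned
by 5, leaving 10,000 retained draws; `BYMConfig.full_scale()` switches to
the production-scale 1,500,000 / 500,000 / thin-100 configuration (same
10,000 retained draws). Disaggregated fractional counts are rounded to the
nearest integer before fitting by default (the total absolute discrepancy
is logged); a gamma-function continuous likelihood is available behind
`count_policy="fractional"` for users who prefer not to round.

Summaries are empirical percentiles (median, equal-tailed 95% interval).
The **fraction of spatial variation** is the posterior median of the
per-draw ratio `var(u)/(var(u)+var(v))`, where `var` is the n−1 empirical
variance across areas; this variance-ratio definition is one of several in
use, so exact numerical agreement with other software's "% spatial" figures
is not claimed. Fitted SIRs are per-area posterior medians of `exp(mu_i)`.

## Diagnostics

Moran's I uses row-standardised weights by default (the spatial-analysis
default; binary available) and a one-sided (greater) permutation test with
999 relabellings, `p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm)`; the
classical normal approximation under the randomisation assumption is
available when p-values below the permutation resolution matter. Isolated
areas are excluded with a warning. Model residuals are Pearson by default
(`(y − E·SIR_fit)/sqrt(E·SIR_fit)`), response residuals optional.

The Geweke score compares the mean of the first 10% of a chain with the
mean of the last 50%, with segment variances taken as AR-estimated spectral
densities at frequency zero (Yule–Walker fits, AIC order selection up to
20) divided by segment length; |z| > 3 is flagged in the pipeline log but
is not fatal.

## Synthetic scenarios

The generator emulates the study conditions at desk scale. The default
nesting 4096 → 1024 → 64 → 16 → 4 is a square-grid analogue of the
Queensland hierarchy (67,047 mesh blocks down to 19 SA4s); each coarser
level merges equal blocks, so membership is exactly nested and coarse
geometries remain rectangles. Finest-level populations are log-normal with
median 82 and log-sd 0.5 (median matching mesh blocks, right-skewed so the
maximum is several times the median), split over the 18 age strata
multinomially around a gently declining share vector; 1% of areas get zero
population to exercise the exclusion rules. The deprivation score is native
at the third-finest (SA2-analogue) level — where such indexes are actually
published — as a planar gradient plus a proper-CAR field, scaled like an
index around 1000.

Counts are generated at the SA2 analogue from the same model family the
fitting stage assumes: `alpha = 0`, quintile effects
(−0.13, −0.23, −0.29, −0.46) matching the magnitude of published SA2-level
deprivation gradients for lung cancer, `u` drawn from a **proper** CAR
field with precision `(D − 0.95 A)/sigma_u^2` (the intrinsic CAR is
improper and cannot be sampled directly; fitting still uses the intrinsic
prior — a deliberate, realistic mismatch), `sigma_u^2 = 0.1`,
`v ~ N(0, 0.01)`. The age-incidence schedule rises exponentially with age
(stylised; real schedules are steeper in middle age) and is scaled so the
state-wide expected total is 1200 cases, putting the finest level at about
0.3 cases per area — the sparse regime of interest. Counts move to all
other levels through the correspondence matrices.

What the generator does **not** emulate: irregular real-world geometries
and neighbour-count distributions, spatially structured age composition,
covariate measurement error, and registry artefacts (late registrations,
geocoding error). Passing tests therefore demonstrate correctness of the
machinery and the qualitative scale-effect mechanism, not calibration to
any real registry's tables.

## Problem sizes and numerical choices

The test suite and the reproduction script run everything at desk scale:
recovery experiments use 200 areas with 60,000-iteration chains (50
replicates), and the cross-level experiments use 12,000-iteration chains
with 2,000 burn-in at the SA1–SA4 analogues — chosen as the smallest sizes
at which the posterior quantiles are stable enough for the comparisons
being made. Model fits at the 4096-area finest level are supported (and
optional behind a flag in the pipeline) but add little beyond runtime for
these checks. Other numerical choices: variance draws are floored at 1e-12;
proposal scales are clamped to [1e-3, 10]; correspondence rows must sum to
1 within 1e-9; Moran's I requires at least 3 connected areas and a
non-constant input; Geweke requires at least 200 draws and 20 per segment.

## Known limitations

- Single-chain inference only; no multi-chain R-hat machinery.
- Intrinsic CAR only (no Leroux/BYM2/proper-CAR fitting option), per the
  model family under study.
- The normal-approximation Moran test uses a dense weight matrix internally
  and is intended for moderate n; the permutation test scales sparsely.
- Coarse levels with very few areas make some quintiles empty, leaving the
  corresponding coefficients prior-dominated — visible as very wide
  intervals at the 4-area coarsest level, which is itself part of the
  scale-effect story.
- Zoning experiments (redrawing boundaries at fixed n) are out of scope;
  only the scaling effect is studied.
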