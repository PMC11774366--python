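# maupbym

Bayesian disease mapping across nested areal aggregation levels, built to
study the **modifiable areal unit problem (MAUP)** when counts are sparse.

Area-level health data are released on administrative geographies, and the
choice of aggregation scale changes the inference: spatial autocorrelation
that is strong at fine resolutions can vanish at coarse ones, and posterior
uncertainty about covariate effects grows as areas are merged. This package
implements the full workflow for quantifying that scale effect on an
Australian-style five-level nested hierarchy (mesh-block analogue up to an
SA4 analogue): population-weighted aggregation/disaggregation of counts and
of an area-level deprivation index, indirect age standardisation, a
from-scratch MCMC sampler for the Besag–York–Mollié (BYM) spatial model,
spatial and convergence diagnostics, and a synthetic-data generator so the
entire analysis runs with no external data. It is aimed at spatial
epidemiologists and biostatisticians who need a controlled environment for
aggregation-sensitivity experiments.

## The model

Observed counts in area *i* follow

```
Y_i ~ Poisson(E_i exp(mu_i)),        mu_i = alpha + x_i' beta + u_i + v_i,
```

where `E_i = sum_k y_k pop_ik / pop_k` is the expected count from indirect
age standardisation (state-wide stratum rates applied to local age
structure) and `SIR_i = y_i / E_i` is the standardised incidence ratio.
`x_i` holds indicators for deprivation quintiles 2–5 (quintile 1, most
disadvantaged, is the reference). The structured random effect `u` has an
intrinsic CAR prior over the binary contiguity structure `w`,

```
u_i | u_{-i} ~ N( sum_j w_ij u_j / sum_j w_ij ,  sigma_u^2 / sum_j w_ij ),
```

and `v_i ~ N(0, sigma_v^2)` is unstructured. `alpha` and `beta` have
N(0, 10^6) priors; both variances have Inverse-Gamma(1, 0.01) hyperpriors.
Sampling is single-chain Metropolis-within-Gibbs: adaptive random-walk
updates for `alpha`, `beta`, `u`, `v` (the latter two site by site, with
per-component mean-centring of `u` each iteration for identifiability) and
conjugate Gibbs draws for the variances. Moran's *I* with permutation
inference measures spatial autocorrelation of observed counts and model
residuals; Geweke scores check chain convergence.

## Worked example

Fit the BYM model with the deprivation covariate at the 64-area SA2
analogue of the default synthetic scenario:

```python
import maupbym as m

data = m.simulate_scenario(m.ScenarioConfig(seed=1))
lv = "sa2"
keep = data.outcomes[lv].E > 0          # drop zero-population areas
outcome = data.outcomes[lv].subset(keep)
adj = data.adjacency[lv].subset(keep)
cov = data.covariates[lv].subset(keep)

chain = m.fit_bym(outcome, cov, adj,
                  m.BYMConfig(n_iter=60_000, n_burnin=10_000, thin=5, seed=1))
summary = m.summarise(chain)
print(summary.params.round(4).to_string())
print(f"fraction of spatial variation: {summary.fraction_spatial_variation:.3f}")
```

which prints

```
          median  ci_low  ci_high  geweke_z
alpha     0.0552 -0.0957   0.2062    0.0789
beta_q2  -0.0703 -0.2798   0.1358    0.2797
beta_q3  -0.2626 -0.4928  -0.0452   -0.3736
beta_q4  -0.3446 -0.5789  -0.1147   -0.4293
beta_q5  -0.4558 -0.7074  -0.2115    0.1374
sigma2_u  0.0120  0.0027   0.0909    1.1560
sigma2_v  0.0127  0.0029   0.0412   -0.3216
fraction of spatial variation: 0.201
```

The posterior medians recover the generative quintile effects
(−0.13, −0.23, −0.29, −0.46): incidence falls as disadvantage diminishes,
with the least-disadvantaged quintile about `exp(−0.456) ≈ 0.63` times the
rate of the reference quintile. `geweke_z` values near zero indicate no
early/late drift in the chain, and the fraction of spatial variation says
about 20% of the random-effect variability is spatially structured at this
level. The full cross-level experiment — ten fits covering every level with
and without the covariate, plus Moran's *I* tables and GeoJSON maps — runs
via the CLI:

```
maupbym run --seed 1 --out results/experiment
```

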