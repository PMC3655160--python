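# Methods

## The spatial-interaction model

`odflows` treats annual OD passenger flow P_ij as the outcome of a
gravity-type process: flow grows with the "mass" of the endpoints (city
population, local purchasing power, network strength/degree/centrality of
the airports) and decays with separation (inverse great-circle distance,
number of stops, haul class). All quantitative covariates enter on the
natural-log scale; betweenness, which can be exactly zero, is offset by +1
before the log (populations, purchasing power, degrees and strengths are
positive by construction, so no offset is applied there). Inverse distance
is 1/km of the endpoint great-circle distance (spherical Earth, radius
6,371 km).

Four specifications share this covariate surface:

1. **Lognormal main effects** — OLS of log P_ij on the main effects; the
   classical log-linear gravity model. Assumes independent homoscedastic
   lognormal flows.
2. **Poisson GLM** (log link) — main effects plus configured two-way
   interactions. Its equidispersion assumption makes prediction intervals
   on large flows extremely narrow.
3. **Negative-binomial GLM** (NB2, log link) — as 2 but with dispersion
   Var = μ + αμ² and α estimated by maximum likelihood.
4. **Lognormal mixed model** — the headline specification: the same fixed
   effects plus three crossed random intercepts, on the origin airport, the
   destination airport and the degree-link-type group. Flows sharing an
   endpoint or a hierarchy stratum are correlated; flows in different
   degree-link-type groups are independent. Degree-link-type dummies are
   excluded from the fixed part of this model because the group random
   intercept would be exactly aliased with them (models 1–3 keep the
   dummies).

The default interaction list is `stops × inv_distance`,
`haul_type × inv_distance`, `stops × same_country` and
`degree_link_type × log_maxc` (dropped automatically for terms that carry a
random intercept). The full categorical cross would be combinatorially
explosive, so the set is configurable rather than exhaustive. All
covariates are retained regardless of significance: the goal is stable
prediction, not parsimonious inference.

## REML for crossed random intercepts

Mixed-model libraries oriented at nested grouping structures handle three
crossed factors with hundreds of levels poorly, so the package fits the
mixed model directly: the restricted likelihood is profiled over the fixed
effects and the residual variance and minimised in the variance ratios
λ_k = σ_k²/σ² (Nelder–Mead on log λ, bounds e⁻¹⁶…e¹⁰). Each evaluation
solves the Henderson mixed-model equations through one Cholesky
factorisation of Z'Z + diag(1/λ) — q×q with q the total number of
random-effect levels — so the cost is independent of the number of rows
beyond the initial cross-products. The implementation is cross-checked in
the test suite against `lme4::lmer(…, REML=TRUE)` on an 800-row fixture;
fixed effects and all variance components agree to five decimals.

Prediction uses the conditional-mean (BLUP) intercept for groups seen in
training, zero for unseen groups. Interval variance on the log scale sums
the fixed-effect variance x'Cov(β̂)x, the residual variance, and per random
term either the BLUP's conditional variance (seen) or the full component
variance (unseen); cross-covariances between BLUP terms are neglected.
Back-transformation is exp(·) — the lognormal *median* — by default,
matching common gravity-model practice; a `mean_correction` flag switches
to the mean-unbiased exp(lp + σ²/2). Count-model intervals are plain
Poisson / negative-binomial quantiles at the predicted mean.

## Network model and route enumeration

The flight network is a directed graph; each scheduled link is present in
both directions with its annual seat capacity as arc weight. Geodesics are
hop counts (the route-choice story is breadth-first search, and distances
weight nothing). Closeness is the inverse mean geodesic distance to the
nodes reachable *from* the airport (computed on the directed graph by
default; an undirected view can be passed instead); betweenness is the
unnormalised shortest-path count with even split across equal-length
geodesics.

Passengers are assumed to take the first minimum-stop path found by BFS
with a deterministic lexicographic neighbour order (any deterministic order
is consistent with "first found"; lexicographic is reproducible across
platforms, and the suite verifies it against exhaustive enumeration). At
most two stops are considered. When both cities have several airports, the
minimum-stop pair wins, ties broken toward the pair with larger combined
strength (passengers prefer bigger hubs). Routes whose endpoint
great-circle distance is under 200 km are excluded (ground transport
dominates); exactly 200 km is retained, since the exclusion rule is
"less than". `n_alternatives` counts distinct minimum-stop paths (not all
paths within two stops). Haul classes: short ≤ 2,000 km < medium <
3,500 km ≤ long.

## Hierarchies and link types

Economic levels are tertiles (33%/67% empirical quantiles, linear
interpolation) of purchasing power per capita; service levels are
quartiles of total airport degree (out/in degree selectable). A value
falling exactly on a break goes to the lower level. Link types are
*ordered* level pairs — "L-H" and "H-L" are distinct, because flows are
directional — giving 9 economic and 16 degree link types.

## The synthetic-data generator

The generator emulates the study system end to end with known parameters:

* **Airports** — log-uniform city populations on [10⁵, 2×10⁷] persons
  (heavy-tailed, bounded, and respecting the 100,000 inclusion floor);
  country labels from spatially clustered groups (dispersion kernels around
  random centres) so "same country" correlates with proximity; purchasing
  power per capita lognormal around a country-level mean (≈2×10⁴ index
  units, country SD 0.6, within-country SD 0.35); total purchasing power is
  per-capita PPP × population × lognormal noise (SD 0.4) — the noise keeps
  log PPP from being an exact linear combination of log PDA and log
  population, mirroring the fact that economic grid cells do not coincide
  with city population counts.
* **Network** — degree-preferential attachment (seed clique, m ≈
  mean_degree/2 links per new node, then preferential densification to the
  target edge count), giving a connected scale-free graph; per-link annual
  seat capacity = 2,000 × (deg_u·deg_v)^0.5 seats, increasing in endpoint
  degrees. Default mean degree 8.
* **Flows** — the generative analogue of the mixed model: log flow =
  fixed-effect linear predictor + origin intercept + destination intercept
  + degree-link-type intercept + Gaussian noise, exponentiated, rounded
  half-up to whole passengers, with sub-1 records dropped (mirroring the
  prediction-stage rule; an unrounded mode supports exactness checks in the
  zero-noise limit). With a sampling fraction f < 1, each itinerary count is
  binomially thinned and rescaled by 1/f, emulating a 10% ticket-sample
  survey rescaled ×10; this is unbiased in expectation.

Default true parameters: population elasticities 0.55, per-capita PPP
0.35, strength 0.25, log max-capacity 0.3, inverse distance 400 km,
same-country 0.8, stop penalties −0.6/−1.2, random-intercept SDs 0.5
(origin), 0.5 (destination), 0.3 (hierarchy group) and residual SD 0.5, all
on the log scale. The intercept (−23) was calibrated once so that generated
flows span all five magnitude categories with the mode in 10³–10⁴ annual
passengers, the shape observed in real itinerary training sets.

What the generator does **not** emulate: real geography (continents,
oceans, ocean-avoiding route kinks), seasonality, airline identity, fares,
demand saturation at hubs, or reporting artefacts of survey data. Passing
tests therefore demonstrate that the pipeline recovers a known
gravity-with-random-effects process from network-shaped data — not that
the model is correct for real air-travel markets.

## Evaluation conventions

* Magnitude categories are decade bins with lower-inclusive boundaries at
  the top of each bin: ≤10², (10², 10³], (10³, 10⁴], (10⁴, 10⁵], >10⁵. The
  published group labels overlap at the decades; this half-open resolution
  is the documented choice.
* The ±30% band is inclusive at both ends.
* The geometric-mean ratio diagnostic is the ratio *of logs*,
  log(x)/log(obs), per its standard phrasing in this literature; a
  `method="log_of_ratio"` flag provides the other reading. Inputs must
  exceed 1 so logs are positive.
* K-fold assignment is a seeded uniform shuffle followed by contiguous
  slicing; fold sizes differ by at most one.
* Multilevel R² follows the proportional-reduction-in-variance scheme:
  level 1 compares σ² + Σσ_k² between the fitted model and an
  intercept-only model with the same random structure; level 2 compares
  σ²/B + Σσ_k², with B the harmonic-mean size of the degree-link-type
  groups (the level-2 stratification). Training-set criteria outside
  cross-validation are computed in-sample.

## Prediction post-processing

In order: (a) predictions exceeding the route's maximum seat capacity are
replaced **by** that capacity (the source description of this rule says
"the product of the maximum capacity", which is read as a typo for plain
replacement — a product with an unstated factor is not computable);
(b) one-stop and two-stop predictions are capped at 140,086 and 8,060
annual passengers, the largest one-/two-stop itinerary counts observed in
mature training markets (a proportional-rescaling alternative is available
behind `mode="rescale"`); (c) predictions below 1 passenger are removed;
then values are rounded half-up. The operation is idempotent, and the
ordering is documented because (c) before (a)/(b) would be equivalent for
caps but not for rescaling.

## Numerical and interface choices

* Quantile method: linear interpolation; ties to the lower level.
* Power-law exponent: least squares of log survival-function versus log
  degree over the distinct observed degrees, reported as the implied
  density exponent (1 − slope); requires ≥10 distinct degrees. The test
  suite checks it against an independent discrete maximum-likelihood
  estimator.
* The degree-preferential generator accepts mean_degree up to n−1
  inclusive (the complete graph), erroring only above it.
* Flows below 1 passenger are invalid as training data (log would be
  negative); `fit` raises on them.
* Seeds: every stochastic routine takes an explicit integer seed; pipeline
  stages derive child seeds from the configured seed, and artifacts embed a
  configuration hash so stages refuse mismatched upstream outputs.

## Problem sizes

The shipped study runs at 300–400 airports, mean degree 8, and ~5,000
observed training flows — the scale at which the full pipeline (route
enumeration over ~80,000 ordered pairs, REML with ~800 random-effect
levels, 10-fold cross-validation) completes in well under a minute per
fit on a single core while leaving every phenomenon of interest
(hierarchy, hubbing, overdispersion, partial observation) present in the
data.

## Known limitations

* Node-level covariates (strength, per-capita PPP, population) are
  identified only through airport-level contrasts once crossed airport
  random intercepts are in the model; with 400 airports their estimates
  carry sampling SDs of a few hundredths even at 5,000 rows. Parameter-
  recovery experiments at that scale measure this variance floor, not
  estimator bias (the zero-noise limit recovers coefficients to 1e-6, and
  the GLS fixed-effect estimator is unbiased at any variance ratio).
* Random-effect prediction neglects cross-covariances between BLUP terms,
  slightly understating interval width for routes whose origin and
  destination are both rare.
* The negative-binomial fit can sit at the α → 0 boundary on
  equidispersed data; coefficients then coincide with the Poisson fit, as
  they should.
* Directional flows are assumed throughout; a symmetrised analysis would
  need to aggregate the OD table first.
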