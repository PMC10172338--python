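# Methods

`nicheshift` models how the abundance of two co-dominant savanna trees —
marula (*Sclerocarya birrea*) and knobthorn (*Senegalia nigrescens*) — varies
with climate, separately for adults and for seedlings (the regeneration
niche), and turns the difference between the two responses into maps and
area accounts of range gain, loss and co-occurrence under current and
future climates.  Because the motivating field data are not public, the
package ships a first-class synthetic-scene generator that reproduces the
statistical structure the analysis assumes, and every stage is tested
against it.

## The abundance model

Counts of individuals per transect, species and size class are modelled as
a zero-inflated negative-binomial (ZINB) mixed model:

    y_t ~ pi * delta_0 + (1 - pi) * NB(mu_t, theta)
    log mu_t = beta0 + beta1 * x_t + beta2 * x_t^2 + offset_t + u_g(t)
    u_g ~ Normal(0, sigma_u^2)

* `x_t` — one climate covariate at the transect midpoint (annual mean
  temperature, max temperature of the warmest month, min temperature of the
  coldest month, annual precipitation, precipitation of the wettest month,
  or potential evapotranspiration).  Covariates are strongly collinear in
  this landscape (|r| ~ 0.5–0.95), so models are single-covariate and
  compared by AIC rather than fitted jointly.
* quadratic response — the vertex `x* = -beta1 / (2 beta2)` of a concave
  fit (`beta2 < 0`) is the climatic optimum: the covariate value of maximum
  predicted abundance.  A convex or flat fit is reported as "no interior
  optimum" with its monotone direction.
* `theta` — NB2 dispersion: variance `mu + mu^2/theta`.  This quadratic
  mean-variance parameterization matches the common default of mixed-model
  count software.
* `pi` — intercept-only structural-zero probability (no zero-inflation
  covariates).
* `u_g` — a random intercept shared by the three transects of a sampling
  grid, capturing unmodelled between-grid variation.

The random intercept is integrated out of the likelihood with **adaptive
Gauss–Hermite quadrature**: for each grid the posterior mode and curvature
of `u_g` are found by damped Newton iteration and 15 Hermite nodes (default)
are centred and scaled there; one node is exactly the Laplace approximation.
The ZINB zero-probability term is not globally concave in `u`, so Newton
steps clamp the curvature and a non-concave mode falls back to the prior
scale for node placement (the quadrature itself remains an exact reweighting
and is validated against brute-force numerical integration to 1e-6).

Fitting is maximum likelihood with L-BFGS-B on
`(beta, log theta, logit pi, log sigma_u)`; the covariate is standardized
internally and coefficients are transformed back to covariate units.  The
warm start is a Poisson IRLS fit plus moment estimates of `theta` and `pi`;
two perturbed restarts (fixed internal seed) guard against local optima.
Boundary solutions (`pi -> 0`, `sigma_u -> 0`) are flagged, not hidden.
The covariance of the estimates is the inverse observed information
(numerical Hessian); Wald `z`, `p` and 95% CIs (`z = 1.959964`) follow.
The paper-style "relevance" rule (p < 0.05 and CI excluding 0) is reported
per coefficient.

Model suites (one model per covariate) are compared by delta AIC with the
conventional "within 2 units = competing" rule; ties rank by fewer
parameters, then input order.  Fit quality is summarized by
variance-partition (marginal/conditional) R2 for count GLMMs, with the
distribution-specific variance taken as `ln(1 + 1/lambda + 1/theta)` where
`lambda = exp(mean linear predictor + sigma_u^2/2)`; which exact R2 variant
the original software used is not documented anywhere we can verify, so the
implemented variant is stated here rather than asserted to match.

### Count modes

Field protocol: trees below 1 m are detected on a 2 m strip, larger trees
on a 40 m strip.  The published procedure multiplies narrow-strip counts by
20 before modelling ("paper" mode).  Multiplying counts before fitting a
count distribution distorts its variance model, so the package default is
"offset" mode — raw counts with `log(strip/40)` as an offset — and the
"paper" mode remains available for exact procedural fidelity.  Predictions
are always on the reference (40 m strip) scale.  The "total" response
(both size classes summed) uses corrected counts, the only scale on which
the two classes are commensurable.

### Prediction

`predict_expected` is population-level by default — random effect set to
zero: `(1 - pi) * exp(beta0 + beta1 x + beta2 x^2)` — matching the typical
use of mixed-model predict functions; a marginal mode multiplies by
`exp(sigma_u^2/2)` (the mean over grids).  Which mode the original analysis
used is unstated; both are parameters and all outputs record the mode.

## Climate gradient and survey design

The sampling gradient is PC1 of a correlation PCA (layers standardized to
zero mean, unit population SD — temperature and precipitation carry
incommensurable units) of annual mean temperature and annual precipitation.
The sign is fixed so that higher scores mean hotter.  Scores are cut into
half-open unit-width bins anchored at the observed minimum (the top value
joins the top bin); a continuous score range like [-2.9, 4) yields seven
strata.  Sampling is restricted to cells whose circular 1 km neighborhood
(cell-center distance; boundary cells use in-bounds neighbors only) is 100%
savanna, and to strata large enough to hold a 2.5 km^2 grid footprint
(erosion test, so thin slivers are excluded).

## Range projection and change classes

A fitted response is projected per-pixel onto the covariate raster and
thresholded to presence at `tau` expected individuals per reference strip
(default `tau = 1`; the published threshold is unstated, so every area
table records the value used).  Seedling-minus-adult differencing yields
four classes that partition the landscape: **gained** (seedlings without
adults), **lost** (adults without seedlings), co-occurrence and absence.
Areas are pixel counts times nominal pixel area in a projected CRS (no
geodesic correction at study scale).  Scenario tables difference seedling
vs adult surfaces *within* each scenario (the uniform reading of the
published table); a future-vs-baseline mode exists but is off by default.
Initial (denominator) areas are the baseline adult ranges.

Future climates are uniform signals: temperature layers shift additively,
precipitation layers scale multiplicatively, and derived layers (PET and
the other bioclim-style layers) shift through their recorded affine
recipes, preserving their noise component.  Named default scenarios use the
projected means for Eswatini under RCP8.5 (+2.3 degC / -3.4% by mid-century,
+4.4 degC / -8.7% by late century); RCP4.5 analogues are set once at
roughly two-thirds of that signal, typical of downscaled regional means for
southern Africa — the source publication states only the RCP8.5 values.

## Spatial diagnostics

Residual spatial dependence is checked with a nonparametric spline
correlogram: Pearson residuals of the ZINB fit (population-level mean and
variance `(1-pi) mu (1 + mu/theta + pi mu)`) are centred/scaled, pairwise
products are regressed on pairwise distance with a cubic B-spline basis
(~sqrt(n) quantile knots), and 95% bands come from bootstrap resampling of
locations (default 1000 replicates; the original count is unstated).
Evaluation runs to half the maximum pairwise distance, where pair density
still supports estimation.  The dependence verdict is "band excludes zero
at any distance below the short-range cutoff".  Residual type and
replicate count are package decisions, documented rather than asserted to
match the original.

## The synthetic scene: what it emulates, and what it does not

`SceneSpec` defaults state one world, chosen once:

* 100 x 100 km landscape, 1 km pixels; annual mean temperature ramps
  west-east over 14–26 degC with pixel noise (SD 0.15 on the unit ramp);
  annual precipitation 600–1400 mm correlated at -0.85 with temperature
  (the hotter lowveld is drier).  The four remaining covariates are affine
  in these two plus noise sized so inter-covariate correlations fall in the
  realistic 0.5–0.95 band — perfect collinearity would make model selection
  vacuous, near-zero correlation would make it trivial.
* 80% savanna cover in smoothed random patches; the 1 km / 100% focal
  filter and footprint test select sampling strata; 6 strata x 7 grids x 3
  transects (400 m long, 200 m apart), grids >= 10 km apart, placed by
  rejection sampling with a 10,000-retry budget (deterministic failure
  beats a silent separation violation).
* Counts are drawn from the generative ZINB model above.  Seedling counts
  are generated on the 2 m strip (mean `mu/20`) so the x20 correction is
  exercised exactly as with field data.  Heights and stem diameters are
  drawn consistently with the generating size class (adults >= 3 m and
  >= 15 cm DBH), so classification round-trips.
* Default truths place optima inside the sampled gradient: marula adults
  at 21.2 degC with broad curvature and seedlings at 19.2 degC (the
  cool-shift / range-tracking signature); knobthorn adults at 22.1 degC and
  seedlings at 22.2 degC with much steeper curvature (regeneration confined
  inside the adult range).  Peak densities give a few hundred detected
  individuals per species over 126 transects, matching the scale of the
  motivating survey.

Not emulated: Gaussian-random-field spatial autocorrelation (noise is
independent pixel noise), fire, herbivory, dispersal limitation, land-use
dynamics, or any cartographic fidelity to a real country.  A green test on
this world establishes that the estimation and accounting machinery is
correct at field-realistic sample sizes — not that any ecological
conclusion about real savannas is reproduced.

## Numerical choices and degenerate inputs

* Linear predictors are clipped at +/-30 before exponentiation.
* `sigma_u < 1e-8` collapses the marginal likelihood to the plain ZINB sum.
* Optimizer bounds: `log theta` in [-4, 12], `logit pi` in [-12, 6],
  `log sigma_u` in [-6, 2.5]; estimates within 0.5 of a bound set boundary
  flags.
* Zero-variance layers, all-zero responses, single-grid tables, orphan
  transect ids and missing covariates raise named errors rather than
  degrade silently.
* Bins, masks and change classes follow half-open / inclusive conventions
  stated in their docstrings; the binarization threshold comparison is `>=`.

## Known limitations

* Wald intervals for `log sigma_u` are unreliable when the ML estimate sits
  on the `sigma_u -> 0` boundary (flat likelihood in the variance
  component); such fits are flagged and their covariance may be singular.
* The single-covariate suite cannot represent joint climate effects; this
  mirrors the motivating analysis, which rejected multi-covariate models
  for collinearity.
* Area accounting assumes a projected CRS with uniform pixel area.
* The spline correlogram tests residual dependence; it does not refit the
  model with a spatial covariance structure.
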