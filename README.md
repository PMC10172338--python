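# nicheshift

Regeneration-niche vs adult-niche modelling for savanna trees along climate
gradients.

Long-lived trees can persist as adults in climates that no longer support
their seedlings.  Comparing where a species *regenerates* with where its
adults stand is therefore a sharper test of whether a range is shifting
than any single snapshot distribution model.  `nicheshift` implements that
comparison end to end for transect count surveys of two co-dominant
southern-African savanna trees — marula (*Sclerocarya birrea*) and
knobthorn (*Senegalia nigrescens*) — and, because the motivating field data
are not public, ships a fully specified synthetic-landscape generator so
every stage is testable and reproducible.

It is aimed at quantitative ecologists who want a tested, scriptable
version of this workflow: stratified transect surveys over a climate
gradient, zero-inflated negative-binomial (ZINB) mixed models of counts,
AIC model selection over collinear climate covariates, suitability
projection and presence differencing, and bootstrap spline correlograms for
residual spatial dependence.

## The model

Counts per transect `t` in sampling grid `g` follow a zero-inflated
negative binomial with a quadratic climate response and a grid random
intercept:

```
y_t ~ pi * delta_0 + (1 - pi) * NB(mu_t, theta),   Var = mu + mu^2/theta
log mu_t = b0 + b1 x_t + b2 x_t^2 + offset_t + u_g,   u_g ~ N(0, sigma_u^2)
```

The random intercept is integrated out by adaptive Gauss–Hermite
quadrature; fitting is maximum likelihood.  For a concave fit (`b2 < 0`)
the climatic optimum is the vertex `x* = -b1 / (2 b2)`.  Per species and
size class, one model per climate covariate is fitted and ranked by
delta-AIC (within 2 units = competing).  The best fits are projected onto
climate rasters, thresholded to presence, and the seedling surface is
differenced against the adult surface: pixels with seedlings but no adults
are **Gained**, adults but no seedlings **Lost** — under the current
climate and under shifted (RCP-style) scenarios.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and exactly what the synthetic world does and does not emulate.

## Worked example

```python
from nicheshift import (SceneSpec, make_scene, build_count_table,
                        fit_covariate_suite, compare_aic, climate_optimum)

scene = make_scene(SceneSpec(seed=1))          # landscape + survey + trees
table = build_count_table(scene.records, scene.design, scene.stack)
fits = fit_covariate_suite("knobthorn", "adult", table)
print(compare_aic(fits)[["covariate", "aic", "delta_aic", "competing"]].head(3))
best = min(fits, key=lambda f: f.aic)
print(climate_optimum(best))
```

```
                covariate         aic  delta_aic  competing
0        annual_mean_temp  320.455690   0.000000       True
1           annual_precip  321.189263   0.733573       True
2  max_temp_warmest_month  336.527357  16.071652      False
```

Annual mean temperature wins the six-model race (annual precipitation is a
competing model at delta-AIC 0.7 — the two gradients are strongly
correlated by construction), and

```
{'optimum': 21.92, 'monotone': None, 'se': 0.25}
```

knobthorn adult abundance peaks at 21.9 °C (true generating optimum:
22.1 °C).  The same scene's seedling model peaks at 22.2 °C with a much
narrower response — regeneration confined inside the adult range — while
marula's seedling optimum sits ~2 °C cooler than its adults', the signature
of a range tracking a warming climate.

The full pipeline (scene → strata → counts → model suites → optima →
scenario projections → area table → correlograms → report) runs from the
command line:

```
nicheshift run --seed 1 --out run1
nicheshift report run1
```

`run1/report.md` then contains the optimum/AIC table above, the gained/lost
area accounting per scenario, e.g.

```
- marula: adult range 8769.0 km2, seedling/adult overlap 8037.0 km2,
  gained 1065.0 km2, lost 732.0 km2 (8% of initial)
```

and a residual-dependence verdict per fitted model ("no evidence of
spatial dependence" for all four responses at seed 1).

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch on the
synthetic scene for a given seed and writes a JSON summary:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All intermediate artifacts (fits, comparison tables, area tables,
correlograms, report) are left under `results/pipeline_seed<seed>/`.
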