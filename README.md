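# batscape

Landscape-scale, temporally dynamic occupancy analysis of acoustic bat
monitoring data.

Statewide acoustic monitoring programs (e.g., the North American Bat
Monitoring Program, NABat) survey a spatially balanced sample of
10 × 10 km grid cells for a few detector-nights each summer.  Detection
is highly imperfect — a cell can be occupied yet yield no identifiable
call files on a given night — so naive detection maps understate and
distort species distributions.  This package implements the standard
remedy at landscape scale: a hierarchical Bayesian **multi-season
(dynamic) occupancy model** linking cell-level landscape covariates to
occupancy while estimating detectability and between-year dynamics, plus
the surrounding machinery a full analysis needs (landscape metrics,
collinearity screening, WAIC model selection, cross-validated AUC,
statewide prediction grids, turnover estimation) and a synthetic-data
generator that emulates the survey design so every stage is testable
without field data.

## Model

For cell *i*, year *t*, night *j*:

```
z[i,1]   ~ Bernoulli(psi1[i]),      logit(psi1[i]) = x[i]' * beta
z[i,t+1] ~ Bernoulli(z[i,t] (1 - epsilon) + (1 - z[i,t]) gamma)
y[i,j,t] ~ Bernoulli(z[i,t] * p[i,j,t]),  logit(p[i,j,t]) = w[i,j,t]' * alpha
```

* `psi` — occupancy probability; `x` holds ecoregion dummies and
  standardized landscape covariates (percent cover of agriculture,
  development, forest, forested wetland; contagion; forest /
  forested-wetland edge density; stream and road-class lengths).
* `p` — nightly detection probability; `w` holds up to nine survey
  covariates (survey type, duration, clutter, date, issue, temperature,
  humidity, wind, rain).
* `gamma`, `epsilon` — colonization and extinction probabilities;
  populations are closed within years, open between years.
* Priors: Normal(0, sd 10) on all logit-scale coefficients,
  Uniform(0, 1) on `gamma`, `epsilon`; all terms fixed effects.

Fitting is Metropolis-within-Gibbs (exact Bernoulli updates of the
latent states, adaptive random-walk Metropolis on coefficients, exact
Beta draws of `gamma`/`epsilon`), with three chains of 25,000
post-burn-in iterations thinned by 4 (18,750 retained draws) by default
and convergence declared at R-hat < 1.1.  Model ranking uses WAIC
computed from the cell-level marginal likelihood (latent states summed
out analytically); weights are normalized relative likelihoods
`exp(-dWAIC/2)`, and models within 2.0 WAIC of the top are closely
competing.  Predictive skill is 5-fold cross-validated AUC with 66%
training splits constrained to contain every ecoregion.

## Worked example

The `analysis/` scripts run the whole procedure on a synthetic 38-cell,
two-year study (generating truth: occupancy rising in forest cover,
detection rising with survey duration, gamma = 0.2, epsilon = 0.15):

```sh
python analysis/01_simulate_study.py
python analysis/02_landscape_covariates.py
python analysis/03_detection_model.py
python analysis/04_occupancy_selection.py
python analysis/05_predictions_turnover.py
```

Representative output (from `02`, `04`, `05`):

```
3 covariate pairs flagged at |r| > 0.7:
  Dev ~ Pri (r = +0.83) -> never in one model
  ...
occupancy models performing at least as well as the null:
model   waic  delta_waic  weight  mean_auc
 F.ED 407.74        0.00    0.56      0.62
 null 410.73        2.99    0.13      0.56
top model 'F.ED': significant effects ['psi:F.ED', 'p:duration', 'gamma', 'epsilon']
turnover summary (posterior mean [95% CrI]):
  gamma     0.351 [0.156, 0.569]
  epsilon   0.126 [0.021, 0.296]
  turnover  0.204 [0.158, 0.237]
```

Reading this: the correlation screen bars development and primary-road
length (r = 0.83) from co-occurring in any model; among the 13 candidate
occupancy models only the forest-edge-density model beats the null
(dWAIC = 2.99, weight 0.56) and carries modest predictive skill
(AUC 0.62 vs 0.56 for the null); and between the two years roughly 20%
of cells changed occupancy state (posterior mean combined turnover 0.20,
decomposed into colonization 0.35 and extinction 0.13).  At 38 cells the
richer models (global, region + land cover) show honest convergence
warnings — exactly the small-sample behaviour a monitoring program's
first years should expect.

A `batscape` console script exposes the same stages
(`simulate`, `metrics`, `screen`, `fit`, `select`, `crossval`,
`predict`); see `batscape --help`.

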