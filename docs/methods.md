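# Methods

## The model and its assumptions

The sample unit is a 10 × 10 km grid cell; the season is a summer survey
year.  Each cell-year has a latent binary state `z[i,t]` (occupied /
used vs not).  First-year occupancy is logit-linear in cell covariates;
between years the state evolves by constant colonization `gamma` and
extinction `epsilon` (a two-state Markov chain), and populations are
treated as closed within a year because each cell is surveyed within a
single week.  Nightly detections are conditionally independent
Bernoulli draws with logit-linear detection probability; a species is
never recorded where `z = 0` (no false positives — a real limitation of
acoustic classification that this model family ignores by construction).

With only two seasons, covariate effects on `gamma`/`epsilon` are not
identifiable in practice, so dynamics are intercept-only constants and
covariates act on first-year occupancy.  Second-year occupancy is the
derived quantity `psi2 = psi1 (1 - epsilon) + (1 - psi1) gamma`.

Region (five physiographic ecoregions) enters occupancy as dummy
variables against a fixed, alphabetically first reference level
("Blue Ridge"), so coefficient values are reproducible; per-region mean
occupancy summaries are coding-invariant.  All continuous covariates are
standardized to mean 0, sample SD 1 (n−1 denominator) on the fitting
set, and the stored location/scale is reused — never recomputed — when
transforming prediction-grid covariates, otherwise predictions would not
be comparable to the fit.

## Fitting

Metropolis-within-Gibbs on the complete-data posterior:

* **Latent states.**  Exact Bernoulli full-conditional updates per
  cell-year, sweeping years in order; a cell-year with ≥ 1 detection has
  `z = 1` with probability 1.  The update is computed in probability
  space (not log-odds) so boundary values `gamma, epsilon ∈ {0, 1}` are
  handled without special cases.
* **Coefficients.**  Componentwise Gaussian random-walk Metropolis on
  `beta` (given `z[:,1]`, a Bernoulli-logit likelihood) and `alpha`
  (given the records at occupied cell-years).  Proposal scales adapt in
  batches of 50 during burn-in toward 0.44 acceptance
  (Robbins–Monro step `1/sqrt(batch)`) and are frozen afterwards, so
  the post-burn-in kernel is a fixed, valid MH kernel.
* **Dynamics.**  `gamma` and `epsilon` have exact Beta full
  conditionals under their Uniform(0,1) = Beta(1,1) priors given the
  latent transition counts, and are drawn by Gibbs.  This is a
  deliberate design choice over random-walk Metropolis: it targets the
  identical posterior, mixes strictly better, and respects the [0,1]
  support by construction.

Priors: Normal(0, sd 10) on every logit-scale coefficient — vague on
the probability scale without being improper — and Uniform(0,1) on the
dynamics.  For the perfect-detection calibration check the package
offers `flat_psi_prior` (intercept-only occupancy): the intercept prior
becomes the standard-logistic density, i.e., exactly flat on `psi`, so
the posterior is the closed-form Beta and the sampler can be validated
against it; `ModelSpec.fixed_p` likewise allows pinning detection at a
known constant (including p = 1, which the logit link cannot represent).

**Schedule.**  Default: 3 chains, 5,000 burn-in iterations, then 25,000
sampling iterations thinned by 4 → 6,250 retained per chain, 18,750 per
model.  (Thinning is applied to the post-burn-in iterations; this is
the only accounting under which those totals are mutually consistent.)
Chains are seeded from independently spawned substreams of one seed, so
runs are bit-reproducible.  Convergence: unsplit Brooks–Gelman–Rubin
R-hat `sqrt(((n-1)/n W + B/n)/W)` per monitored parameter
(coefficients, `gamma`, `epsilon`; not the data-constrained `z`),
declared converged below 1.1.  Failure is a recorded warning, never an
exception — mirroring how a monitoring analysis reports rather than
discards a poorly identified term.  Constant chains are flagged
degenerate instead of computing R-hat.

## Model selection

The procedure is two-stage: detection covariates are selected first
(each candidate fitted with intercept-only occupancy, ranked by WAIC)
and then frozen while the occupancy candidate set is fitted — 11
a priori ecological models plus null and global.  Wetland-associated
species substitute forested-wetland cover/edge density for the upland
forest terms.

WAIC uses one pointwise unit per **cell** (years pooled), with the
latent states marginalized analytically via the forward recursion —
never conditioned on sampled `z`, whose well-known instability in
conditional WAIC this avoids.  `lppd` is computed by log-sum-exp;
`p_waic` uses the sample (n−1) variance.  Weights are normalized
relative likelihoods `exp(-dWAIC/2)`; the competing set is
`dWAIC ≤ 2.0`; ties keep input order.

The Pearson screen flags covariate pairs with |r| > 0.7; a flagged pair
may not co-occur in one model.  The global model is assembled in a fixed
covariate order, dropping any covariate flagged against one already
included.  If a sampled dataset flags a pair *inside* an a priori model
(possible at n = 38, where sample correlations fluctuate), that model
cannot be tested as posed and is dropped with a warning — the analogue
of excluding a road class from all models after a screen.

**Cross-validation.**  5 random partitions, train fraction 0.66 with
round-half-up sizing (25 train / 13 test of 38), drawn by rejection
until every ecoregion appears in training; the same partitions are
reused for every species and model.  Each fold refits the model
(standardizing on the training cells only), scores held-out cell-years
by posterior-mean occupancy, and labels them by observed detection
(naive occupancy) — the only observable label, with the known
consequence that low detectability biases AUC toward 0.5.  AUC is the
rank-based Mann–Whitney statistic with half-credit for ties; a
single-class fold is recorded as undefined and excluded from the mean.
Pooled-year AUC is the headline; year-specific values are also emitted.

## Landscape metrics

Rasters are categorical class grids (ESRI ASCII format, 30 m pixels by
default) representing the already-buffered cell extent.  Conventions,
fixed for bit-reproducibility:

* adjacency is 4-neighborhood, interior pairs only (landscape boundary
  excluded), double-counted so the class adjacency matrix is symmetric;
* percent cover is over non-NODATA pixels of user-supplied aggregated
  classes (e.g., pasture/hay + cultivated crops → Ag), summing to 100;
* edge density = meters of focal/non-focal shared boundary per hectare
  of landscape;
* contagion = `[1 + sum q ln q / (2 ln m)] * 100` with
  `q_ik = P_i g_ik / sum_k g_ik` and `0 ln 0 := 0`; undefined (error)
  for single-class landscapes.

Stream and road lengths are accepted as precomputed columns; vector GIS
processing is out of scope.

## The synthetic-data generator

The generator emulates the survey structure the analysis assumes:
38 cells (configurable) across five ecoregions, two years, four
stationary + two mobile nights per cell-year (subsets emulate
single-method cells), latent dynamics by the same Markov chain the
model fits, detections with a logit-linear nightly model over the nine
survey covariates, and an optional missingness rate for occasions lost
to weather or malfunction (no field value exists for this rate; the
default is 5%).  Landscape covariates are drawn from a Gaussian copula
whose default correlation matrix reproduces the collinearity the screen
must catch (development with road classes ≈ 0.75–0.8, wetland cover
with its edge density 0.85), truncated to physical bounds with percent
covers rescaled to sum ≤ 100.  Covariate locations/scales are loose
caricatures of a southeastern-US mixed forest/agriculture state.
Rasters come from iid categorical fields aggregated by 3 × 3 majority
smoothing (the smoothing-pass count is the clustering knob; ties keep
the current class, then lowest code).

What it does **not** emulate: spatially balanced (GRTS) cell selection,
spatial autocorrelation among cells, acoustic misclassification / false
positives, observer or site effects, and real geographic geometry.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the model's own assumptions — not robustness to their
violation in field data.

## Problem sizes and numerical choices

Generating values used by the analysis scripts and checks: occupancy
intercept 0.3 with forest slope 0.9 (standardized scale), detection
intercept −0.2 with duration slope 0.6 (mean nightly p ≈ 0.45;
cumulative per cell-year ≈ 0.95), gamma 0.2, epsilon 0.15.  The
parameter-recovery study runs 50 replicates of 200 cells at a reduced
3 × 2,000 schedule; the analysis scripts and the acceptance script use
38 cells at 3 × 1,200 (thin 4), sizes chosen so a complete run is a
desk-scale computation.  The marginal likelihood is computed in linear
probability space (products of ≤ 6 Bernoulli terms cannot underflow
meaningfully) and returns −inf for genuinely impossible histories;
pointwise likelihood matrices are evaluated vectorized over draws in
chunks of 2,000 to bound memory.  Cross-validation fold refits derive
their seeds from the base seed (base + 1000·fold) so whole runs are
reproducible file-for-file.

## Known limitations

* Constant dynamics: no covariates on `gamma`/`epsilon`, no
  autologistic second-year term; defensible at two seasons only.
* No spatial random effects or autocorrelation; cells are exchangeable
  given covariates.
* The no-false-positive assumption is optimistic for automated call
  classification.
* WAIC's cell-level pooling treats the two years of one cell as a
  single predictive unit; other poolings are defensible and would shift
  WAIC values.
* Componentwise Metropolis mixes slowly for strongly collinear
  covariates — one motivation for the |r| > 0.7 screen, but models with
  many region dummies at 38 cells can still show R-hat warnings, which
  are reported, not suppressed.
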