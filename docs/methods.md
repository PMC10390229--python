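# Methods

## The model

Visual turf quality ratings are ordinal: a rater walks the trial during a
*rating event* and assigns each plot an integer from 1 (poorest) to 9 (best).
Treating these integers as interval-scaled measurements conflates three
things the program cares about separately: how good the cultivar is, how
severe the rater was that day, and how the 9 categories partition the
quality continuum. `turfrsm` models the ratings on a latent logit scale with
an adjacent-category (Rasch rating-scale family) likelihood. After
re-indexing ratings to categories 0..M (M ≤ 8), the log-odds between
adjacent categories are

    ln( Pr[Y_ni = s] / Pr[Y_ni = s-1] ) = theta_n - beta_i - tau_s

* `theta_n` — perceived quality of plot *n*, decomposed as
  `theta = eta[cultivar(n)] + LOC_n`;
* `eta_k ~ Normal(0, sigma^2)` — intrinsic cultivar effects;
* `LOC ~ MVN(0, K)` — spatially correlated plot-location effects with
  `K_ij = alpha^2 exp(-d_ij^2 / (2 rho^2)) + delta_ij sigma_e^2`, `d_ij` the
  Euclidean distance between plot centres;
* `beta_i` — severity of rating event *i* (positive = severe);
* `tau_s` — threshold where categories s-1 and s are equally probable.

`beta` and `tau` carry sum-to-zero constraints (the last element is
structurally the negative sum of the others), which anchors the latent zero
at the trial's average quality level and makes scales comparable across
locations under the assumption that average levels agree.

Normalising the adjacent log-odds gives the category probabilities

    p_s = exp(s*c - T_s) / sum_r exp(r*c - T_r),   c = theta - beta,
    T_s = tau_1 + ... + tau_s,  T_0 = 0,

computed with max-subtraction in log space so extreme latent positions
cannot overflow. `theta` has no time index: quality is modelled as constant
over the trial and temporal variation loads on `beta`; a seasonal quality
component is out of scope (see Limitations).

`M` is fixed at 8 (the capacity of the 1-9 scale) rather than the observed
maximum, so thresholds stay comparable across events and locations;
categories never observed contribute only prior information to their
thresholds. Disordered thresholds (negative category widths) are reported as
a diagnostic, never silently corrected.

## Priors

Weakly informative throughout: half-Student-t(3, 0, 1) on `sigma`, `alpha`,
`sigma_e` (the positive-scale reading of a t3(0,1) prior);
Inverse-Gamma(5, 5) on `rho`. The free components of `beta` get
Normal(0, 1) and those of `tau` Normal(0, 2): thresholds span several logits
in practice while event severities rarely exceed ±1, and both scales are
configurable through `PriorConfig`.

## Inference

The posterior is sampled with the package's own no-U-turn sampler
(`turfrsm.sampler`): slice-variant tree doubling, dual-averaged step size
targeting 0.8 acceptance, and Stan-style windowed estimation of a diagonal
mass matrix. The model is sampled on an unconstrained vector with

* non-centred cultivar effects (`eta = sigma * eta_raw`),
* non-centred spatial effects through the covariance Cholesky factor
  (`LOC = L z`), with hyperparameter gradients propagated by forward-mode
  differentiation of the Cholesky factor, `dL = L Phi(L^-1 dK L^-T)`,
* log-transformed scale parameters with Jacobian terms,
* sum-to-zero completion of the free `beta`/`tau` components, so every
  retained draw satisfies the constraints exactly (to floating tolerance).

All gradients are analytic and are property-tested against finite
differences. The default protocol is 4 chains x 1,000 iterations, the first
500 discarded as warmup and the remainder thinned by 2, i.e. 250 retained
draws per chain. Convergence is summarised by split R-hat (arviz,
`method="split"`) and bulk ESS for every scalar parameter and the log
posterior; constant chains are flagged NaN rather than reported as
converged. Divergent transitions are counted and reported in the run
metadata, never raised.

The normative density is `turfrsm.model.log_posterior`, a fully normalized
natural-scale density; the sampler's unconstrained density differs from it
only by the documented transforms.

## Synthetic trials and the recovery study

`simulate_trial` generates a complete trial from the generative model:
cultivar effects, an RCBD plot grid (one replicate of every cultivar per
grid row, unit plot spacing, plot centres at `(col, row)`), a GP field over
the grid, a monthly event calendar in which raters cycle deterministically
(event *e* is rated by rater *e* mod R, so each event's true severity is its
rater's fixed severity), and inverse-CDF sampling of each rating. RNG use is
ordered (cultivar effects, plot permutations, field, ratings) so seeds are
portable.

The default recovery design (`recovery_study_config`) is 3 replications of
10 cultivars rated monthly for 5 years by 5 raters: 30 plots, 60 events,
1,800 ratings; `sigma = 0.7`, `(alpha, rho, sigma_e) = (0.15, 2.5, 0.2)`,
severities evenly spaced on [-0.8, 0.8], 8 thresholds evenly spaced on
[-2, 2]. The severity grid sums to zero per rater cycle, so per-event
severities satisfy the model's sum-to-zero constraint whenever the number of
monthly events is a multiple of the number of raters; other configurations
are rejected with a suggestion rather than silently recentred. An
`all_raters_each_month` option generates the denser variant in which every
rater rates every month.

What the generator does *not* emulate: missing ratings, rater dropout,
temporal drift in severity, seasonal quality cycles, or non-grid layouts
with physical plot dimensions. Passing recovery tests therefore show
identifiability under the model's own assumptions, not robustness to these
real-data features.

## Recovery evaluation

`recovery_report` computes, per scalar parameter (10 eta, 30 LOC, 60 beta,
8 tau, sigma, alpha, rho, sigma_e — 112 in the full design), the posterior
2.5/50/97.5% quantiles of `draw - truth` and counts intervals excluding
zero. Under correct calibration each interval excludes its truth with
probability ~5%, so a handful of exclusions among ~112 parameters is the
expected behaviour of a correct implementation, not a defect; runs of the
full design here typically show 4-7 exclusions, and the convergence
criterion (max split R-hat rounding to 1.0) is met comfortably.

The test suite runs the recovery design at half length (30 monthly events)
with the full sampling protocol to keep the suite inside a practical
runtime; the acceptance script runs the full-length design. Problem sizes:
900 observations, 82 monitored parameters (tests); 1,800 observations, 112
parameters (acceptance script).

## Baseline comparison

`fit_lmm` fits the conventional comparator `Y = eta + u + eps` (fixed
cultivar means, random event intercept, REML via statsmodels MixedLM) on the
raw 1-9 scale with cell-means coding. Under a balanced design its cultivar
standard errors are identical by construction — the uniform-SD property the
latent-scale model improves on. `compare_cultivar_means` reports Pearson and
Spearman correlations between the two models' cultivar means (average-rank
ties; undefined correlations for zero-variance inputs are returned as NaN).

## Diagnostics

All diagnostic outputs are plain tables. Category widths are successive
threshold differences (they telescope to `tau_M - tau_1`); severity trends
are LOWESS curves of per-event severity means against month-of-year
(default span 0.6, raters with more than 3 events), pooling years because
exact rating dates are generally unavailable; spatial maps place LOC
posterior means on the (row, col) grid; cross-location tables align
cultivars on each location's zero-centred logit scale without rescaling.

Variance partitioning has no single canonical definition for this model;
the package uses the across-observation variance of each linear-predictor
component (cultivar, severity, spatial) per posterior draw, expressed as
percentages of their sum and averaged over draws. The percentages sum to
100 by construction; a fit in which all three components are constant is
reported as degenerate rather than divided by zero.

## Numerical choices

* Probability normalisation subtracts the max log-weight; adjacent-logit
  identities hold to 1e-10 over randomized draws, oracle agreement to 1e-12.
* `sigma_e = 0` is disallowed for hyperparameters; covariances built with a
  nugget below 1e-9 receive 1e-9 jitter with a warning.
* Duplicate plot coordinates warn (the nugget keeps K positive definite);
  duplicate (plot, event) observations are an error.
* NUTS: max tree depth 10, divergence threshold 1,000 on the energy error,
  warmup windows 75/25-doubling/50, mass-matrix regularisation toward 1e-3.
* Initial values: uniform(-0.5, 0.5) on the unconstrained scale, with log
  scale parameters shifted down by 1 so chains start at sub-unit scales.

## Limitations

* No seasonal/temporal quality component; severity absorbs it.
* One parameter per rating event: severity is not pooled within rater, so
  raters are only characterised through their events.
* Exact GP over plots: fine for trials up to a few hundred plots, not for
  thousands.
* The sampler is single-threaded; chains run serially.
* Real NTEP layouts need a coordinate convention (plot-length units); when
  only row/column indices are available, unit spacing is assumed.
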