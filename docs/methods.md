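# Methods

`lpisim` is a simulation laboratory for one question: if vertebrate
populations that declined for half a century started to recover, would a
Living-Planet-style geometric-mean abundance index — computed from sparse,
noisy monitoring series — let us detect *that* the trend changed, *how
steeply* it changed, and *when*?  The package simulates the data, builds the
index, fits the detection model, and sweeps the full experimental grid.

## Scenario model

Every scenario trajectory `I(t)` is piecewise log-linear on calendar years,
normalised to `I(1970) = 1`, with at most one slope change at the
intervention year 2020:

* **Historical segment (1970–2020).**  `log10 I(t)` falls linearly so that
  `I(2020) = 1 − D`, with decline fraction `D` set by the historical class:
  extreme 0.95, strong 0.70, moderate 0.50, small 0.20.  The pre-intervention
  slope is therefore `β_pre = log10(1 − D)/50` per year (−0.026 for extreme,
  −0.0019 for small declines).
* **Future segment (2020–2050).**  Four scenarios set the post-intervention
  slope `β_post`: *business as usual* continues `β_pre`; *stabilization* is
  flat (`β_post = 0`); *recovery* returns to the 1970 baseline by 2050
  (`β_post = −log10(1 − D)/30`); *partial recovery* restores half of the
  log10 deficit by 2050 (`β_post` half the recovery slope).  The partial
  scenario is defined this way because it is the simplest interpolation that
  keeps all four scenarios log-linear and strictly ordered at 2050
  (recovery > partial > stabilization > bau).

## Synthetic populations

Each simulated population `i` tracks the trajectory multiplicatively:
`N_it = b_i · I(t) · 10^ε_it`, with a population-specific base abundance
`log10 b_i ~ Normal(2, 0.5)` (so typical abundances of ~100 in arbitrary
units) and observation error `ε_it ~ Normal(0, σ_obs)` on the log10 scale.
Defaults: `σ_obs = 0.1` log10 units (roughly ±26% multiplicative error, a
plausible magnitude for count-survey error) and one population per species.
There is no process noise, density dependence, demographic stochasticity or
between-population trend variation: every population shares the scenario
trend exactly, so the mixed model's random-intercepts structure is correctly
specified for these data.  Passing tests therefore demonstrate estimator
correctness under the stated generative model, not robustness to trend
heterogeneity, taxonomic/geographic bias, or autocorrelated process noise —
all of which real monitoring data have.

Monitoring imperfection is imposed by `degrade_sampling`: each series keeps
a random observation window whose length is geometric with mean 15 years
(clipped to [2, available years]), starting uniformly over feasible years,
and within the window each year is observed independently with probability
0.7 ("fullness").  Draws leaving fewer than two points are redrawn (up to
100 attempts, then the window endpoints are kept) so dataset size stays an
exactly controlled factor.  All of these are configuration knobs; the
defaults above define the package's study conditions.

All randomness flows from a single integer seed per dataset
(`SamplingSpec.seed`); simulation and degradation draw from independent
child streams of that seed, so the same seed always reproduces the same
dataset bit-for-bit.

## Index engine

The index follows the standard chained geometric-mean construction:

1. **Annualisation.**  Series with ≥ 6 observations get a penalised
   B-spline smooth (GAM) of log10 abundance with basis dimension half the
   series length (minimum 3), evaluated at every year of the span; the
   penalty weight is chosen by generalised cross-validation over a log-spaced
   grid.  Shorter series use log-linear interpolation between observations
   (the chain method).  Exactly representable (noise-free) series make the
   Gaussian GAM iteration degenerate; they are annualised by chain
   interpolation, which is exact for such data.  Zeros are handled by the
   standard convention: if any value in a series is 0, 1% of the series mean
   is added throughout.
2. **Growth rates.**  `d_t = log10(N_t / N_{t−1})`, labelled by the end year
   of the interval and clipped to ±1 (one order of magnitude per year), the
   conventional outlier guard for geometric-mean indices.
3. **Aggregation.**  Rates are averaged arithmetically (on the log scale)
   over populations within species, then over species — unweighted, since
   the simulated world has no realm/taxon structure — and chained:
   `I_baseline = 1`, `I_t = I_{t−1} · 10^{D̄_t}`.  A year with no monitored
   species breaks the chain; the index is reported missing from there on.
4. **Uncertainty.**  Species are resampled with replacement (default 1000
   bootstrap replicates); per-year 2.5th/97.5th percentiles of the resampled
   indices form the envelope.

Because rates are within-population ratios, the index is invariant to each
population's absolute scale, and permutation of species or populations never
changes any output.

## Broken-stick change-point model

Detection fits population-level log10 abundances (not the aggregated index:
the mixed model needs grouping structure, and fitting the raw series keeps
per-series information) with a piecewise-linear fixed-effect trend,

    log10 N_it = a + β_pre (t − τ) + (β_post − β_pre) max(0, t − τ) + u_i + e_it,

time centred at the candidate intervention year τ.  Random effects are per
series: intercepts plus pre/post slopes where estimable, falling back to
intercepts only when the richer fit does not converge or is degenerate
(residual variance ≈ 0 makes random slopes unidentified; with the default
generator the slope variances are truly zero, so the fallback is the
correctly specified model and is taken in most noisy replicates — always
flagged in the output).  Estimation is maximum likelihood, not REML, so
log-likelihoods are comparable across τ; slope intervals are Wald 95%.

τ is estimated by profile likelihood over an integer-year candidate grid
(default 2010–2045, clipped strictly inside the observed span):

* the model is refit at every grid year with the intercepts-only structure,
  warm-starting each fit from the previous year's optimum (a two-stage
  choice: the intercepts-only scan is an order of magnitude faster and its
  profile has the same maximiser in practice; a full random-slopes scan is
  available via `scan_structure="slopes"`);
* `τ̂` maximises the scan log-likelihood, and `ci_tau` collects the grid
  years within 1.92 log-likelihood units of the maximum (the χ²₁/2 drop for
  a 95% profile interval);
* the winning year is refit with the full random-effects ladder for the
  reported slopes and their intervals.

Degenerate limit: candidate years where the model fits exactly (residual
scale < 1e−10, only possible for noise-free data) have unbounded likelihood
in the limit, so they dominate the profile; if several such years exist the
profile is flat among them and `ci_tau` spans them all.  This reproduces the
expected behaviour at both ends: noise-free recovery data give `τ̂ = 2020`
with a point interval, and no-break (business as usual) data give an
interval spanning the whole grid — there is no intervention year to find.

## Experimental sweep and summaries

`run_experiment` crosses historical classes × future scenarios × dataset
sizes (default 100/500/1000 species) × end years (default 2030–2050 in
5-year steps, so detection can be assessed from 10 years after the
intervention) × replicates (default 100; desk-scale work uses ~20).  Each
cell's seed is derived from the master seed and the cell coordinates via a
`SeedSequence` spawn key, so any cell can be re-run in isolation and match
the full sweep, and re-running the whole grid is byte-identical.  Cell
failures are caught, recorded in an `error` column and logged; they never
abort the sweep.  Per-cell timing goes to the structured log, not the
results table.

Summaries per (historical, future, size, end year) group — and optionally
pooled across end years for display — report the median, the 2.5%/97.5%
quantiles of the point estimates (thick bars), and the same quantiles of the
Wald/profile interval endpoints (thin bars), computed only over converged
fits with linear-interpolation quantiles (stated in the output header;
groups with no converged fit are flagged, not fabricated).  The figure
renderer draws the point-plus-two-bars panels with rows = historical
classes, columns = sizes, colours = future scenarios, dashed lines at the
generating truth, and omits business-as-usual from intervention-year panels.

## Numerical choices and problem sizes

* Mixed-model optimiser: L-BFGS with ML; it is both faster and finds better
  optima than the library default on these data.  Non-convergence triggers
  the random-effects fallback ladder; if every rung fails the cell is
  returned unconverged with estimates absent.
* Quantile convention: linear interpolation everywhere.
* The stochastic recovery checks in the test suite use 20 replicates of 500
  species (recovery scenario, end year 2050, default noise and degradation)
  under the extreme and small historical classes — large enough for stable
  medians, small enough for a desk run.  At that scale the median `|τ̂ −
  2020|` is 0 years under extreme declines, the median post-intervention
  slope is within a few percent of truth, and detection accuracy is ordered
  extreme ≤ small, matching the qualitative expectation that stronger
  historical contrast is easier to detect.
* The bootstrap envelope and the GAM path are exercised on small fixtures;
  the sweep defaults (100 replicates, three sizes, five end years) are a
  production configuration and take correspondingly longer.

## Known limitations

* No taxonomic or geographic structure, no covariance between populations,
  no process noise by default: detection performance here is an upper bound
  relative to real data with heterogeneous trends.
* The GAM smooth rounds the slope change at the intervention year, so
  index-level round trips through the smoothing path are approximate near
  the kink (the chain path is exact).
* `ci_tau` is a grid-resolution profile interval; it cannot be narrower than
  one year and is not a bootstrap interval.
* The broken-stick model assumes exactly one slope change; multiple change
  points and driver covariates are out of scope.
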