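# lpisim

Can a multi-species abundance indicator tell us when biodiversity starts to
recover?  `lpisim` is a simulation study of that question for
Living-Planet-style indices: it generates vertebrate-like population time
series that declined between 1970 and 2020 and then follow one of four
future scenarios, degrades them to the sparse, noisy, ragged coverage that
real monitoring data have, aggregates them into a chained geometric-mean
index, and asks a broken-stick mixed-effects model to recover the
post-intervention trend and the year the trend changed.

It is aimed at quantitative ecologists and indicator developers who want to
measure — rather than assume — the detection power of an abundance index
under controlled conditions.

## The model in brief

Scenario trajectories are piecewise log-linear with one slope change at the
intervention year τ = 2020:

    log10 I(t) = β_pre · (t − 1970)                      1970 ≤ t ≤ 2020
    log10 I(t) = log10 I(2020) + β_post · (t − 2020)     2020 < t ≤ 2050

with `β_pre = log10(1 − D)/50` for historical decline fraction
D ∈ {0.95, 0.70, 0.50, 0.20} (extreme/strong/moderate/small), and `β_post`
set by the future scenario: business as usual (`β_pre` continues),
stabilization (0), partial recovery (half the deficit restored by 2050) or
recovery (return to baseline by 2050, `β_post = −log10(1 − D)/30`).

Populations track the trajectory with lognormal observation error
(`N_it = b_i · I(t) · 10^ε`, `ε ~ N(0, 0.1)` on the log10 scale) and are
subsampled to windows of geometric mean length 15 years with 70% of years
observed.  The index is the standard chain: annualise each series (GAM
smooth of log10 abundance for series with ≥ 6 points, log-linear
interpolation otherwise), take annual log10 growth rates clipped to ±1,
average within species then across species, chain from 1 at the baseline,
and bootstrap species for a 95% envelope.

Detection fits log10 abundance with a linear mixed-effects model with a
slope change at a candidate year τ (series-level random effects, maximum
likelihood) and profiles τ over an integer grid: τ̂ maximises the profile
log-likelihood and its 95% interval is the set of years within 1.92 units
of the maximum.  See `docs/methods.md` for the full account.

## Worked example

Closed-form truths for one scenario:

```bash
$ lpisim scenario-info --historical extreme --future recovery
{
  "decline_fraction": 0.95,
  "slope_pre": -0.026020599913279617,
  "slope_post": 0.04336766652213269,
  "index_2020": 0.050000000000000044,
  "index_2050": 1.0
}
```

An extreme decline loses 95% of the index by 2020 (−0.026 log10 units per
year); full recovery by 2050 needs +0.043 log10 units per year.

Simulate a 100-species monitoring dataset under that scenario (noisy and
degraded by default), compute the index, and fit the change point:

```bash
$ lpisim simulate --historical extreme --future recovery --n-species 100 --seed 5 --out demo.csv
wrote 100 series to demo.csv

$ lpisim index demo.csv --smoothing chain --n-boot 200 --seed 5 --out demo_index.csv
index at final year: 0.6676 (baseline 1970 = 1)

$ lpisim fit demo.csv --dialect wide --grid-first 2010 --grid-last 2045 --out demo_fit.csv
tau_hat=2020 ci_tau=(2020, 2020) slope_post=0.04223
```

The profile search puts the intervention exactly at 2020 and estimates the
post-intervention slope at 0.0422 against a generating value of 0.0434 —
the change point and recovery rate are detectable from 100 sparse series.
The index itself (0.67 at 2050 rather than 1.0) illustrates how much a
chained index computed from short, ragged windows can drift from the
underlying trajectory even when the model-based estimates are accurate.

The full experimental sweep, its summary table, and the point-plus-bars
panel figure:

```bash
lpisim experiment --set replicates=20 --out cells.csv
lpisim summarize cells.csv --pool-end-years --out summary.csv
lpisim figure summary.csv --quantity slope_post --out slopes.svg
lpisim figure summary.csv --quantity tau_hat --out tau.svg
```

Everything is also available as a library (`lpisim.build_trajectory`,
`simulate_populations`, `degrade_sampling`, `growth_rate_table`,
`compute_index`, `bootstrap_index`, `fit_broken_stick_at_tau`,
`profile_intervention_year`, `run_experiment`, `summarize_estimates`).

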