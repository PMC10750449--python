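# Methods

## Overview

`hale-ensemble` projects age- and sex-specific healthy life expectancy
(HLE/HALE) forward in time with a probabilistic ensemble of 21 individual
projection models. The workflow is the three-step pseudo-Bayesian-model-
averaging scheme used in probabilistic life-expectancy forecasting:

1. **Holdout validation.** For each (country, sex) stratum, part of the
   observed 1990–2019 panel is withheld; every model is fit on the
   remainder and projected over the withheld years. A model's *projection
   bias* is the mean, over withheld years, of (median projected HLE at
   birth − observed HLE at birth).
2. **Weighting.** Model weights are `w_m = exp(−|bias_m|)`, normalized to
   sum to one — an operational stand-in for the posterior model
   probability `PR(H_m | D)`. Models with larger holdout bias are
   exponentially down-weighted.
3. **Pooled projection.** Every model is refit on the *full* window and
   1000 posterior simulations of future age-specific HLE are drawn per
   model. Pooled simulations are drawn as a mixture: pick a model with
   probability `w_m`, then take one of its whole trajectories (all ages and
   horizon years together) without replacement where possible. Medians are
   point projections; 2.5th/97.5th percentiles form the 95% credible
   interval, using linear-interpolation percentiles.

All modeling is done directly on the HLE scale (years) with Gaussian
likelihoods, not on underlying mortality/morbidity rates.

## The model catalog

The 21 members and their families (stable ids):

| ids | family | definition |
|-----|--------|------------|
| 1–2 | age-time | `h(a,t) = α_a + δ (t−t̄)` with a common drift (1) or per-age drifts `δ_a` (2) |
| 3–4 | weighted age-time | model 2 fit by weighted likelihood, each year's contribution ∝ `ρ^(T−t)`, ρ = 0.90 / 0.95, weights normalized to mean 1 |
| 5–6 | weighted age-time-cohort | as 3–4 plus a penalized random-walk cohort effect over `c = t − a` |
| 7–14 | piecewise | age intercepts + continuous piecewise-linear common time trend; {no cohort, cohort} × {1, 2 knots} × {knots fixed at window quantiles, SSE-optimal search} |
| 15–16 | age-time-cohort | per-age drifts + cohort effect with first- (15) or second- (16) difference penalty |
| 17–21 | Lee-Carter | `h(a,t) = α_a + β_a k_t` (level-scale): classic SVD, two-component, broken drift (increments after the training midpoint), robust (median-increment) drift, age-cohort extension |

Normalizations and identification:

* Lee-Carter: `Σ β_a = 1`, `Σ k_t = 0`; drift estimated from `k_t`
  increments; `k_t` forecast as a random walk with drift, with the drift
  itself drawn from `N(d̂, se²)` per simulation.
* Cohort effects: sum-to-zero and zero-slope constraints (standard APC
  identification), imposed as heavily weighted constraint rows; a
  first-/second-difference roughness penalty (dimensionless strength 10,
  differences scaled by the gap between consecutive observed cohorts)
  handles sparsely observed cohorts. Cohorts unobserved in training are
  continued as a random walk from the last fitted effect, with the
  innovation scale estimated from the fitted cohort increments.
* Piecewise knot search: candidate knots keep a 3-year margin per side;
  the 2-knot search uses a coarse (every-other-year) grid with a minimum
  3-year gap, and for cohort variants the search is profiled on the
  cohort-free design before a single full refit.

**Posterior approximation.** Linear-in-parameters families sample
parameters from `N(θ̂, σ̂² (M'M)⁻¹)` (the Gaussian posterior implied by the
penalized least-squares fit, the penalty acting as a Gaussian prior), then
propagate the sampled parameters through the future design; Lee-Carter
families propagate random-walk-with-drift innovations. A full MCMC backend
was deliberately not built: the Gaussian approximation keeps 21 models ×
404 strata at desk scale and is exact for the unpenalized linear members.
Draws represent the *underlying* age-specific HLE (no observation noise is
re-added) and are clipped to `[0, ω]` with ω = 110.

**Degenerate inputs.** A constant series makes cohort designs rank
deficient; the minimum-norm least-squares solution pins the redundant
parameters and a warning is logged. A degenerate (zero-variance) Lee-Carter
first component falls back to `β_a = 1/A`, `k_t = 0`.

## Holdout orientation

The default orientation trains on the earliest years and withholds the
latest 13 (1990–2019 → train 1990–2006, test 2007–2019), the standard
forecast-validation direction. A `literal` orientation is also provided
that withholds 1990–2002 and trains on 2003–2019, projecting *backwards*
by time-reversing the series; which direction the original scheme intended
is ambiguous, so both are implemented and neither is asserted as canonical.
Bias is computed at birth only — the quantity the projections are
validated and reported on; per-age components are retained for diagnostics.

## Synthetic data generator

The generator emulates a GBD-style HALE export with known ground truth.
Defaults are the study conditions: 202 countries, both sexes, ages
0, 1, 5, …, 80, years 1990–2019.

* **Baseline age profile.** Each country draws a latent development score;
  hazards are an infant rate (median ≈ 0.018/yr, strongly
  development-dependent) plus background and Gompertz components
  (`1e−4 · e^{0.085a}`), sex-scaled (female ×0.85, male ×1.25); the healthy
  fraction declines linearly from ≈0.97. HLE is obtained by Sullivan-type
  closed-form integration of the piecewise-constant schedule, so the
  cross-age profile is coherent by construction, and a high infant hazard
  reproduces the empirical HLE(0) < HLE(1) crossover.
* **Time dynamics.** A per-age linear drift on the HLE scale, proportional
  to the baseline profile, with birth-drift mean 0.25 yr/yr and
  cross-country SD 0.10 (≈2.5 years per decade globally, with enough
  dispersion that a small tail of countries declines). The `broken` regime
  re-scales the drift by U(0.3, 1.7) after a random knot year; the
  `cohort` regime adds a sinusoidal birth-cohort wave (amplitude 0.4 yr,
  period 45 yr). Applying the trend on the HLE scale (rather than to the
  hazards) keeps noiseless series exactly linear in calendar time, which
  makes the generating drifts exactly recoverable by OLS — the property
  the recovery tests rely on.
* **Noise.** Stationary AR(1) observation noise on the HLE scale
  (marginal SD 0.2 yr, ρ = 0.3), independent across ages. Rare
  noise-induced violations of the age-monotonicity invariant are repaired
  by descending sort within (country, sex, year) above age 1 — a no-op on
  noiseless data.

What the generator does **not** emulate: GBD uncertainty intervals
(point values only), real cross-country correlation structure, mortality
shocks/pandemics, non-stationary noise, or realistic per-country levels.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the generator's assumptions, not fidelity to any real
country's HALE.

## Numerical conventions

* Percentiles: linear interpolation between order statistics (so for
  draws 1…1000 the 2.5th percentile is 25.975); fixed because CrI
  endpoints differ across conventions at n = 1000.
* Headline outputs are rounded half-up to one decimal.
* Rank tables: rank 1 = highest HLE; ties broken by country-identifier
  order (deterministic, flagged in the output; measure-zero under
  continuous draws).
* Pooling keeps whole trajectories per simulation to preserve cross-age
  and cross-year coherence; zero-weight models are dropped before
  sampling, so their draws are provably irrelevant.
* Stage seeds derive from the master seed as
  `SeedSequence((master, stage, stratum, model))`, all below 2³¹.

## Problem sizes used in the test suite

Monte-Carlo suites run on reduced panels chosen to make the checks sharp
yet quick: coverage uses 200 replicate single-country panels (8 ages, iid
noise) with the pooled 95% interval checked against the noiseless truth 11
years out; ensemble-superiority uses 51 panels cycling the three trend
regimes with the 13-year holdout, 300 draws per model and 1000 pooled
simulations. The acceptance script runs the full default conditions
(202 countries × 2 sexes, 21 models, 1000 simulations).

## Known limitations

* The catalog is a faithful reconstruction of the stated family counts
  (2 age-time, 4 weighted, 8 piecewise, 2 age-time-cohort, 5 Lee-Carter),
  not a replica of any particular predecessor's supplementary equations;
  the 4 weighted models split 2 + 2 between age-time and age-time-cohort.
* Parameter posteriors are Gaussian approximations; heavy-tailed or
  multimodal posterior shapes are out of reach.
* On cohort-regime panels the future cohort wave is unpredictable from
  the identified cohort effects (new cohorts enter at birth), so all
  models share an error floor and the ensemble's edge over the average
  model narrows — visible as the near-ties in the superiority check.
* Weights are estimated per stratum from a single holdout window; no
  cross-validation over multiple windows is attempted.
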