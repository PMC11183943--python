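# Methods

## The estimand

The depletion rate of a species × date × sampling-round cell is

    D = 1 − V_open / V_bagged,

where `V_bagged` and `V_open` are the cell's *expected* standing-crop
volumes under the two treatments. D is a functional of model expectations,
not of individual flowers: its posterior describes the mean depletion rate,
never the distribution of per-flower depletion. Because a posterior draw can
put the open expectation above the bagged one — and "negative depletion" has
no biological meaning — the per-draw values are censored at zero *before*
summarization. Censoring therefore biases the posterior of D upward under a
true null; the null-calibration test quantifies this (posterior medians
stay well below 0.15 when true D = 0).

## Normalization

Every volume is divided by the arithmetic mean bagged volume of its
species × round × date cell, zeros included. Including zeros is the reading
consistent with D being defined on unconditional standing-crop means; the
hurdle model separately accounts for zero inflation, and because D is a
within-cell ratio the choice cannot bias D in expectation (the test suite
confirms that fits on raw and normalized volumes give overlapping 95%
intervals for D). Cells with no bagged observations, or whose bagged flowers
are all empty, carry no information about relative depletion; both arms are
excluded in full and reported.

The normalizer is a sample statistic, so with few bagged flowers per cell it
is noisy; this inflates apparent residual dispersion (absorbed by the gamma
shape) but not the treatment contrast, which both arms of a cell share.

## The hurdle-gamma model

Let v ≥ 0 be a normalized volume, z = 1 when v = 0. With observation-level
linear predictors η_h (logit scale) and η_g (log scale):

    z ~ Bernoulli(π),            logit(π) = η_h
    v | z = 0 ~ Gamma(α, α/μ),   log(μ)   = η_g        (mean parameterization)

Both predictors share one structure: a fixed coefficient per
treatment × round cell (cell-means coding — D is a per-cell functional, so
this avoids any baseline-choice ambiguity), plus varying intercepts and
varying *treatment-slope* deviations for tree, species and date. The
treatment contrast is the only within-group contrast guaranteed by the
design, which is why it is the slope that varies. Deviations are
parameterized non-centered: for group level j of factor g,

    (u_int, u_slope)_j = diag(σ_g) · L_g · z_j,   z_j ~ N(0, I₂),

with L_g the Cholesky factor of a 2×2 correlation matrix (correlation
modelled by default, switchable off). The unconditional expected volume
implied by one draw is E[V] = (1 − π)·μ; cell expectations used for D
include the cell's species and date deviations and marginalize tree
deviations to zero (the typical-tree cell mean, matching reporting by
species × day × hour).

### Priors

Regularizing and weakly informative, all overridable via `PriorConfig`:

| parameter | prior | default | rationale |
|---|---|---|---|
| fixed effects (both link scales) | Normal(0, 1) | mean 0, sd 1 | after normalization the bagged gamma cells sit near 0 on the log scale; ±2 sd spans volume ratios of ~1/7–7 and hurdle probabilities ~0.1–0.9 |
| group SDs σ | Half-Normal(1) | scale 1 | weak shrinkage; keeps funnels mild |
| intercept–slope correlation ρ | LKJ(2) | η = 2 | gently favours small |ρ| |
| gamma shape α | Exponential(ln 2) | median 1 | α ≈ 1 (exponential-like skew) typical for standing-crop volumes; thin tail regularizes |

This prior set keeps the induced prior on D broad over [0, 1).

### Sampling

Inference is adaptive Hamiltonian Monte Carlo with analytic gradients of the
joint log posterior (hand-derived; verified against finite differences in
the test suite): leapfrog integration with a diagonal mass matrix, dual
averaging of the step size toward 0.8 acceptance, mass re-estimation at 40%
and 70% of warmup from accumulated draw variances (shrunk toward unity),
trajectory length ≈ 1.2 time units with the step count jittered ±20% to
avoid resonance, and an energy-error threshold of 1000 for declaring a
trajectory divergent. Defaults: 4 chains, 1000 warmup + 1000 retained draws.
Chains are seeded as `default_rng([seed, chain])`, making every fit
bit-reproducible.

Diagnostics are rank-normalized split R-hat and bulk/tail ESS (ArviZ).
Thresholds (defaults R-hat ≤ 1.01, bulk ESS ≥ 400 on fixed effects, ≤ 2%
divergent trajectories) are attached to the result as warnings and raised
as `ConvergenceWarning` — never silently ignored; the CLI's `--strict` flag
turns them into a non-zero exit.

Correctness of the sampler is defined by oracles, not by equivalence to any
particular implementation: on single-cell non-hierarchical instances the
posterior factorizes enough to evaluate by brute force on a dense grid
(`nectardep.oracle`), and marginal posterior means from HMC agree with the
grid to well under 2%.

## The synthetic-data generator

The generator is a statistical mirror of the analysis model, not a
mechanistic foraging/secretion model. Per tree it draws hurdle zeros and
gamma positives with hierarchical intercept and slope deviations on the same
link scales the model uses (so parameter recovery is well-posed). The true
depletion d of a (date, round) acts on the open arm's *unconditional* mean,
split between the two processes on the ratio scale:

    (1 − π_open)/(1 − π_bagged) = (1 − d)^f,   μ_open/μ_bagged = (1 − d)^(1−f),

with f = 0.5 by default (how much real depletion is whole-flower emptying
versus partial draining is unknown; f is a simulation knob, not an
estimate). Treatment-slope deviations then perturb both open-arm link
scales; because foragers never *add* nectar, each tree's open unconditional
mean is capped at its bagged mean, which keeps every realized cell depletion
in [0, 1). `TrueParameters` records the exact per-cell expectations actually
used, so recovery tests always compare posteriors against generative means,
never against noisy per-flower ratios.

Default design (`default_config`): four species (plum, blackthorn, cherry,
pear) with baseline positive-volume means 0.3–1.0 μL and gamma shapes
1.5–1.8 (sub-microliter, right-skewed standing crops typical of rosaceous
tree flowers); nine sampling days following the flowering phenology
(plum → blackthorn → plum + cherry → pear); 1–5 trees per species-day;
rounds at 9:00–15:00 every 2 h with one extra 17:00 round on the final day;
five bagged + five open flowers per tree-round (1460 observations);
baseline empty-flower probability 0.15; a diel depletion schedule rising
from 0.1 (9:00) to 0.6 (15:00); hierarchy SDs 0.2–0.3 for intercepts and
0.1 for slopes on both link scales.

The dew option models the final sampling day: a fixed dew volume (default
9 μL) mixes into each flower's nectar before the first round, then water
evaporates geometrically (default 30%/h), so °Brix concentrations start
near 1–3% and climb through the day. Mixing uses the volume-fraction
approximation to °Brix (error < 15% below ~35 °Brix); sugar mass is
conserved exactly, and dilution followed by evaporation back to the original
volume restores the original concentration to machine precision. Dew
affects only the recorded concentrations, not the volumes entering the
depletion analysis.

What the generator does **not** emulate: secretion/removal dynamics within
a round, within-tree spatial structure, flower age and dehiscence effects,
weather-driven covariance between depletion and temperature, or
measurement error in reading microcapillary tubes. Passing recovery tests
therefore demonstrate that the *inference machinery* is calibrated for data
matching the model's assumptions — not that the model is correct for any
particular field dataset.

## Recovery-study problem sizes

The replicated recovery study (tests and `scripts/acceptance.py`) uses a
reduced design: 2 species × 3 dates × 3 trees per species-date, 4 rounds,
and 20 flowers per treatment per tree (2880 observations, 24 cells per
replicate), fit with a single HMC chain of 350 warmup + 350 draws. Twenty
flowers per tree-round (4× the field protocol) is the per-cell sample size
at which ±0.1 recovery of cell medians is statistically attainable; at the
field protocol's 5 + 5 the sampling noise of the cell means alone exceeds
that band. Slope SDs are zero in these runs so that the scheduled d is
exactly the true cell depletion; intercept SDs stay at realistic values.
The test suite runs 20 constant-D replicates plus one diel and one null
replicate (~6 min on one CPU); the acceptance script runs 12 (~3 min).

## Weather suitability

An hour is suitable for honey bee foraging when temperature ≥ 10.0 °C
(inclusive — only *below* 10 °C disqualifies), precipitation ≤ 0 mm by
default (any appreciable precipitation disqualifies; the cutoff is a knob
for noisy station data), and the clock hour falls in a fixed daylight
window, 07:00–19:00 by default (an operational convention — no astronomical
sunrise computation). The headline quantity is suitable daylight hours over
all daylight hours. Simulated weather defaults (mean 8 °C, ±5 °C diel
amplitude, 30% of hours with showers) approximate erratic early spring in
central Germany and put roughly half of daylight hours below the foraging
thresholds.

## Numerical choices and edge cases

- Zero volumes are exact zeros (the hurdle); volumes are validated ≥ 0 on
  input and missing concentrations are parsed as missing, never as 0.
- Intervals are equal-tailed quantile intervals (not HPD): reproducible
  without density estimation and nested by construction. Censoring is
  applied per draw, before summarization.
- ρ = tanh(c) is clamped away from ±1 by 1e-9 and the Cholesky term
  √(1−ρ²) floored at 1e-6 to avoid overflow at the edge of the correlation
  space; the LKJ prior makes this region negligible.
- Non-finite log posteriors during leapfrog integration are treated as
  divergent trajectories and rejected.
- A dataset with no bagged observations anywhere, or with no cell
  containing both treatments, is rejected as unidentifiable before sampling.
- Cells reported are exactly those present in the data; no interpolation to
  unsampled rounds.

## Known limitations

- The sampler is a fixed-length HMC, not NUTS; very stiff posteriors (tiny
  group SDs with many levels) mix more slowly and may need longer warmup.
- With a single chain, R-hat is undefined and `fit` skips the diagnostic
  table; replicate studies accept this trade-off for speed, relying on the
  calibration checks instead.
- The 17:00 round appears only where sampled; cells are never imputed.
- The dew model treats dew volume as constant across flowers of a day and
  ignores runoff; it is a qualitative generative option, adequate for the
  concentration trajectory's shape but not for quantitative dew physics.
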