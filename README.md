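# nectardep

Inference of **nectar depletion rates** from pollinator exclusion
experiments, for ecologists studying floral resource limitation and
competition between pollinators.

In an exclusion experiment, some flowers are bagged in fine mesh (excluding
insect visitors) while neighbouring flowers stay open. The bagged flowers
show the *potential* nectar standing crop; the open flowers show the
*realized* standing crop after foraging. Their contrast is the depletion
rate

```
D = 1 − V_open / V_bagged
```

where `V_bagged` and `V_open` are the expected (mean) standing-crop volumes
of a species × date × sampling-round cell. `D` is a proxy for the intensity
of competition among pollinators: near 0 when nectar is abundant relative to
foraging pressure, near 1 when foragers strip flowers as fast as nectar is
secreted.

## What the package does

- **`nectardep.data_io`** — tidy CSV schemas for flower-level nectar
  observations (date, round, species, tree, treatment, volume in μL,
  optional °Brix concentration) and hourly weather records, with strict
  validation and lossless round-trips.
- **`nectardep.synthetic`** — a generative mirror of the analysis model for
  testing and power analysis: hurdle zeros, gamma positive volumes,
  tree/species/date hierarchy on the link scales, a diel depletion schedule
  for open flowers, optional dew dilution of concentrations, and weather
  series — all with recorded ground truth (`TrueParameters`).
- **`nectardep.preprocess`** — the cell-wise normalization: every reading is
  divided by the mean bagged volume of its species × round × date cell;
  degenerate cells (no bagged arm, or an all-empty bagged arm) are excluded
  and reported.
- **`nectardep.hurdle`** — the hierarchical Bayesian **hurdle-gamma model**:
  a logit-scale binomial submodel for whether a flower is empty and a
  log-scale gamma submodel for positive volumes; treatment × round cell
  means as fixed effects; varying intercepts and treatment slopes for tree,
  species and date (non-centered, with optional intercept–slope
  correlation); regularizing weakly informative priors. Inference is by an
  adaptive Hamiltonian Monte Carlo sampler with analytic gradients
  (`nectardep.sampler`), with split-R-hat/ESS diagnostics via ArviZ and a
  brute-force grid-posterior oracle (`nectardep.oracle`) for validating the
  sampler on small instances.
- **`nectardep.depletion`** — the censored posterior of `D` per cell
  (negative draws mapped to 0, since negative depletion has no meaning) and
  point-interval summaries: median with nested equal-tailed 66% and 95%
  credible intervals.
- **`nectardep.weather`** — honey bee foraging suitability (an hour is
  suitable when ≥ 10 °C, without appreciable precipitation, during
  daylight) and the fraction of suitable daylight hours.
- **`nectardep.cli`** — a `nectardep` command with `generate`, `fit`,
  `report` and `weather` subcommands driven by one YAML config and one
  global seed.

## Worked example

Simulate a study-scale dataset (4 rosaceous tree species over 9 spring
sampling days, 5 bagged + 5 open flowers per tree per 2-hourly round, with
true depletion rising through the day), normalize, fit, and summarize:

```python
import nectardep as nd
from nectardep.hurdle import ModelSpec, SamplerConfig
from nectardep.depletion import depletion_table, estimates_to_frame

obs, truth = nd.simulate_dataset(nd.default_config(seed=1))   # 1460 rows
normalized, excluded = nd.normalize(obs)                      # 0 cells excluded
spec = ModelSpec(rounds=(9, 11, 13, 15, 17))
draws = nd.fit(normalized, spec,
               SamplerConfig(chains=2, warmup=500, draws=500), seed=1)
cells = sorted(set(zip(obs.species, obs.date, obs.round_hour)))
table = estimates_to_frame(depletion_table(draws, cells))
print(table[table.date == "2023-03-29"].round(3).to_string(index=False))
```

which prints (one row per species × date × round cell):

```
   species       date  round_hour  d_median  d_l66  d_u66  d_l95  d_u95  n_draws
blackthorn 2023-03-29           9     0.000  0.000  0.000  0.000  0.050     1000
blackthorn 2023-03-29          11     0.163  0.000  0.309  0.000  0.432     1000
blackthorn 2023-03-29          13     0.283  0.137  0.404  0.000  0.506     1000
blackthorn 2023-03-29          15     0.508  0.396  0.596  0.285  0.676     1000
      plum 2023-03-29           9     0.000  0.000  0.000  0.000  0.076     1000
      plum 2023-03-29          11     0.200  0.032  0.338  0.000  0.466     1000
      plum 2023-03-29          13     0.312  0.173  0.428  0.000  0.528     1000
      plum 2023-03-29          15     0.526  0.418  0.617  0.285  0.698     1000
```

`d_median` is the posterior median of the censored mean depletion rate for
that cell; `d_l66/d_u66` and `d_l95/d_u95` are the nested 66% and 95%
equal-tailed credible intervals. The generator's realized truth for these
cells rose from D ≈ 0.03 at 9:00 to D ≈ 0.55 at 15:00, and the posterior
medians track that diel rise. (At these short chain lengths `fit` attaches
convergence warnings on some fixed effects; the defaults — 4 chains,
1000 warmup + 1000 draws — run clean.)

The same pipeline from a shell:

```sh
nectardep generate --config config.yaml --seed 1
nectardep fit      --config config.yaml --observations out/observations.csv
nectardep report   --config config.yaml --draws out/draws.csv \
                   --observations out/observations.csv
```

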