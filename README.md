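# radflow

**Generalized radiation model (GRM) for human migration** — calibration,
population forecasting and amenity backcasting for locality systems where
population alone is a poor proxy for a place's pull on migrants.

## The problem

The classic radiation model (RM) predicts the expected migrant flow from
locality *i* to locality *j* as

```
⟨T_ij⟩ = T_i · p_i p_j / ((p_i + s_ij)(p_i + p_j + s_ij))
```

where `T_i` is the number of out-migrants of *i*, `p` is census population and
`s_ij` is the population strictly closer to *i* than *j* is (the intervening
opportunities). Population stands in for economic opportunity — an assumption
that breaks down in developing countries and wherever people move for quality
of life, tourism-driven employment or counterurbanization.

The GRM keeps the radiation functional form but replaces population with a
trainable **urbanization index**

```
U_i = Σ_k w_k f_ik
```

over normalized locality features `f_k` — population, population density and
per-type amenity counts (schools, offices, shops, leisure, tourism, health).
The feature weights `w_k` and the per-locality migrant fractions `α_i`
(`T_i = α_i p_i`, with `α_i ∈ (0,1)` enforced by a logistic parameterization)
are fitted by gradient descent on the mean squared error between observed and
predicted inter-census population change

```
Δp_i = (b − d) p_i + Σ_r ⟨T_ri⟩ − Σ_r ⟨T_ir⟩
```

with `b`, `d` the annual birth and death rates. Forecasts are iterated
annually (the per-interval prediction divided by the calibration span), with
amenity counts re-projected each year from population-within-radius features
through per-amenity backcast regressions, and model configurations are ranked
by the mean absolute percentage error (MAPE) of forecast populations.

The package is aimed at researchers in human mobility, spatial demography and
epidemiological modelling who need origin–destination flow estimates and
locality-level population forecasts from census tables, centroids and
amenity counts.

## Library layout

| module | contents |
|---|---|
| `radflow.radiation` | haversine distances, intervening mass, RM/GRM flow equation, national-scaling baseline |
| `radflow.features` | feature tables, the four normalizations (min-max, adjusted z, logistic z, percentile), urbanization index, Ward feature grouping/reduction |
| `radflow.calibration` | loss, exact analytic gradients, SGD/Adam fitting, realization batteries |
| `radflow.forecasting` | annualized iterative forecasts with per-year feature re-projection |
| `radflow.amenities` | population-within-radius features and the five-family backcast regressions |
| `radflow.evaluation` | MAPE, relative improvement, ANOVA / Welch t-test comparison, relative feature weights |
| `radflow.synthetic` | seeded synthetic locality systems with known migration truth |
| `radflow.benchmark` | the end-to-end synthetic study harness |
| `radflow.io`, `radflow.cli` | CSV/JSON formats and the `radflow` command |

Randomness uses numpy's PCG64 (`default_rng`); every component of the
synthetic generator draws from its own `SeedSequence([seed, stream])`
substream, so outputs are byte-identical across platforms for a given seed
and adding amenity types never perturbs populations.

## Worked example

```python
import numpy as np
from radflow import (SyntheticScenario, make_benchmark_data, run_benchmark)

scenario = SyntheticScenario(n_localities=150, seed=42)
data = make_benchmark_data(scenario, eval_steps=1)   # truth 2007 -> 2010 -> 2013
result = run_benchmark(data, n_realizations=3, seed=0)
print(result.comparison.report())
```

prints

```
model comparison (MAPE %, mean +/- sd over realizations)
  grm: 0.7194 +/- 0.0325 (n=3)  [+55.22% vs rm]
  rm: 1.6066 +/- 0.0008 (n=3)  [+0.00% vs rm]
  baseline: 5.8018 +/- 0.0000 (n=3)  [-261.12% vs rm]
  one-way ANOVA: F=41744.1214, p=3.711e-13
```

Reading: on a 150-locality system whose true migration flows are driven by
amenities, the GRM forecasts 2013 populations with 0.72% mean MAPE over three
training realizations, beating the classic RM (1.61%) and the baseline that
scales every locality by the national growth rate (5.80%). The ANOVA row
tests whether the MAPE distributions of the three models differ.

The same pipeline is available from the shell:

```sh
radflow synthesize --seed 7 --out runs/demo
radflow train      --seed 7 --out runs/demo
radflow forecast   --seed 7 --out runs/demo
radflow evaluate   --seed 7 --out runs/demo
radflow compare    --seed 7 --out runs/demo
```

Each subcommand accepts `--config config.json` (see `radflow.io.RunConfig`)
and writes CSV/JSON artifacts plus a `run.json` with the config hash, seed
and version needed to reproduce them bit for bit.

### File formats

* locality CSV: `id,name,latitude,longitude,land_area_km2,pop_<year>[,pop_<year>…]`
* feature CSV: `locality_id,<feature>,…` (non-negative reals)
* flows CSV: `origin_id,destination_id,flow`
* trajectory CSV: `year,locality_id,population`
* fitted parameters, run configs, scenarios: JSON

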