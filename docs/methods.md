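# Methods

## Model

The radiation model treats migration as a sequential search over
opportunities: the expected flow from origin *i* to destination *j* is

    ⟨T_ij⟩ = T_i · m_i m_j / ((m_i + s_ij)(m_i + m_j + s_ij)),

with `m` the attractiveness mass of a locality and `s_ij` the total mass of
localities strictly closer to *i* than *j* is, excluding both endpoints. In
the classic model `m` is census population; in the generalized model it is
the urbanization index `U_i = Σ_k w_k f_ik` over normalized features. The
model is scale-free in `m` (multiplying all masses by a constant leaves flows
unchanged), so fitted weights are identified only up to a positive scale;
interpretation should rely on signs and relative magnitudes.

Distances are great-circle (haversine, spherical Earth, R = 6371.0 km, no
ellipsoid correction) between locality centroids. The circle boundary is
open: a locality exactly at distance `d_ij` from the origin does not count
toward `s_ij`. This convention preserves two useful exact identities that
the tests assert — every origin's nearest destination sees zero intervening
mass, and the row sums telescope to `T_i · M₋ᵢ/(m_i + M₋ᵢ)` where `M₋ᵢ` is
the total mass of all other localities. Ties are measure-zero for continuous
coordinates; scans break them deterministically by stable id-order sorting.

## Normalization

Raw features span orders of magnitude, so each is normalized independently:

* **min-max**: `log1p` then affine rescale to [0, 1];
* **adjusted z-score**: `log1p`, z-score, translate right, clip at 0. The
  translation is `+σ` of the logged values by default, with a documented
  `shift="one"` option that adds 1 instead (one standard deviation *of the
  z-score*); the two coincide only when σ = 1, and the clipping threshold
  differs accordingly;
* **logistic z-score**: the standard logistic of the z-score, in (0, 1). The
  z-score is taken on `log1p` values by default — consistent with the other
  magnitude-based methods and the heavy right tails of amenity counts — with
  `on_log=False` for the raw-scale variant;
* **percentile**: average ranks (ties averaged) scaled as `(r − 1)/(n − 1)`.

Population (not sample) moments are used throughout, for determinism and to
match the closed-form unit-test values. Constant features normalize to all
zeros (min-max, adjusted z) or all 0.5 (logistic z, percentile) with a logged
warning: the pipeline stays total and never divides by zero. Normalization
statistics are frozen at calibration time and re-applied to projected feature
tables during forecasting, because the trained weights are only meaningful on
the calibration scale. For the percentile method the frozen statistic is the
sorted calibration sample; new values receive their average rank within it.

## Calibration

Trainable parameters are the weights `w_k` (free reals) and migrant fractions
`α_i` with `T_i = α_i p_i`; `α` is stored as unconstrained pre-activations
mapped through the logistic, so it is strictly inside (0, 1) at every step by
construction. The objective is the mean squared error of the per-locality
population change over the census interval,

    Δp̂_i = g·p_i + Σ_r ⟨T_ri⟩ − Σ_r ⟨T_ir⟩,   g = (1 + b − d)^Δ − 1,

with compounding of the net vital rate over the Δ-year interval by default
(a simple-rate option exists; the choice matters little at the few-percent
rates typical of the domain). Weights can drive some `U_i` non-positive while
the flow equation requires positive masses, so masses are floored at
ε = 1e−9 with a warning; the gradient through the floor is defined as zero.

Gradients are exact closed forms, not numerical: the loss is backpropagated
through the flow equation including the path through the intervening mass
`v_ij` (each mass `m_k` enters `v_ij` for every pair whose circle contains
*k*; the scatter is accumulated with tie-aware prefix sums over the fixed
per-origin distance orderings). One loss+gradient evaluation is O(n²) after
an O(n² log n) one-time sort. A finite-difference test verifies every partial
derivative to 1e−4 relative error.

Two optimizers are provided: plain constant-step full-batch SGD (the default)
and Adam. The loss is in persons², so its raw gradient scale varies by
dataset over many orders of magnitude; the benchmark and recovery
configurations use Adam (learning rate 0.05, 300–600 epochs), which needs no
per-dataset step tuning. Initialization: weights half-normal |N(0, 0.1)| and
α ≈ 0.05 with small seeded jitter on the pre-activation. The positive weight
start matters: normalized features are non-negative, so a zero-mean draw can
put every urbanization index below the ε-floor, where the weight gradient
vanishes identically and training never moves the weights; a positive start
guarantees an interior point while leaving weights free to turn negative
during training. Mini-batching over localities
restricts which squared residuals enter the objective; the flow computation
is always global because every residual depends on all origins.

α is per-locality by default (n + K parameters from n observations — the
model can interpolate Δp almost exactly, which is intended: forecast quality,
not residual size, ranks models). For parameter-recovery experiments a
`shared_alpha` option fits a single fraction, matching the constant-α truth
of the synthetic scenarios and making the weight-recovery problem
well-posed.

## Forecasting

The calibrated model predicts a Δ-year change; annual forecasting divides
the raw prediction by the calibration span (3 by default) and iterates:
project amenity counts for the previous year's populations through the
fitted backcast models, recompute population density from the fixed land
areas, re-normalize with the frozen statistics, evaluate Δp̂ with the
previous year's vital rates, annualize, update, floor at zero (with a logged
count of floored localities). Population-within-radius covariates are
recomputed from the evolving forecast populations each year. The
national-scaling baseline simply multiplies every locality by the national
growth rate and is the degenerate case of this loop with uniform rates and
no migration.

## Amenity backcasting

Amenity counts are predicted from the number of residents within 1 km and
5–50 km (5 km steps) of each centroid, by centroid inclusion (d ≤ r, self
included). Targets are `log1p(count)`. Five families compete per amenity:
linear regression, RBF support-vector regression, gradient boosting,
k-nearest neighbours and a power law; the winner is the best test R² on a
seeded 80/20 split, ties broken by the fixed family order. The four generic
families regress on `log1p` of the eleven radii features — on this scale an
amenity exactly equal to a radii feature is exactly linear, and the
log-transform suits the heavy-tailed covariates. The power-law family
regresses `log1p(count)` on `ln(population within 1 km)`, the nearest-radius
analog of locality population. Hyperparameter grids are intentionally tiny
(SVR C ∈ {1, 10}; boosting depth ∈ {2, 3}; k ∈ {3, 5}) and config-editable.
Predictions are inverse-transformed with `expm1`, floored at zero, and kept
real-valued until export.

## Synthetic data

The generator emulates a developing-country locality system at desk scale:

* centroids uniform over a bounding box spanning an archipelago-sized region
  (no coastline geometry — a stated non-goal);
* populations log-normal with median 32,000 (log-sd 1.1) and land areas
  log-normal with median 100 km² (log-sd 0.9), matching the positively
  skewed size distributions of national census data;
* amenity counts `round(c_a · pop^β_a · e^ε)` with per-type exponents β in
  0.8–1.3 (urban-scaling range), coefficients giving tens-to-hundreds of
  counts for a median locality, and lognormal noise σ = 0.5 that is a fixed
  per-locality field — a locality keeps its idiosyncratic surplus of each
  amenity as it grows, so truth amenities evolve deterministically with
  population;
* migration truth generated by the generalized model itself with known
  weights (amenity-driven: population weight 0) under logistic z-score
  normalization, constant migrant fraction α = 0.05 per three-year census
  interval, and annual birth/death rates 2.25%/0.55%.

Default problem sizes — 200 localities, 10 realizations or recovery seeds,
one three-year evaluation interval — were chosen as the smallest system on
which the spatial structure of the model (hundreds of interacting circles)
is non-trivial while a full study runs in minutes on one core.

What passing tests on this generator do **not** show: real amenity data has
spatial autocorrelation, coverage bias and category correlations that the
generator omits, and real migration is not generated by any radiation-family
model. In particular, the synthetic POI count correlates with population far
more strongly (Spearman ≈ 0.96) than observed in national OSM data (≈ 0.3),
and the true-model advantage of the GRM over the RM on synthetic truth is
larger than one should expect on censuses. The synthetic benchmark validates
the machinery — recoverability, conservation, ordering — not empirical
effect sizes.

## Numerical choices and limitations

* Intervening-mass ties use strict inequality; tie-breaking in sorted scans
  is deterministic by id order.
* Flows, populations and amenity counts are real-valued internally; rounding
  to integers happens only on CSV export.
* The telescoping identity is asserted at 1e−9 relative tolerance; oracle
  equivalence tests compare against O(n²)–O(n³) brute-force loops at n ≤ 20.
* MAPE requires strictly positive actual populations; zero-population
  localities must be filtered upstream.
* ANOVA and Welch t-tests are reported without multiplicity correction;
  with 100 realizations per configuration, differences in the third decimal
  of MAPE can be "significant" — read effect sizes, not p-values.
* Feature weights from different normalization methods are not directly
  comparable (different feature scales); relative weights `w_k / Σ|w_j|`
  within one configuration are.
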