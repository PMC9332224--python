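# Methods

`teacrop` couples a water-driven crop simulator parameterised for tea
(*Camellia sinensis*) with a regression benchmark on plot-level plucking
records, plus a seeded generator that produces both kinds of input with
known ground truth. This note documents the model, its assumptions, the
defaults and the numerical choices.

## Reference evapotranspiration and thermal time

ET0 follows the daily FAO-56 Penman–Monteith procedure for the grass
reference surface. Sub-model choices, all standard for data-sparse
stations:

- soil heat flux G = 0 at the daily step;
- actual vapour pressure `ea = es · RHmean/100` (only mean relative
  humidity is recorded at stations like the one emulated here; the
  dew-point route is not used);
- net shortwave with albedo 0.23 from measured solar radiation;
- net longwave via the FAO-56 Stefan–Boltzmann term with clear-sky
  radiation `Rso = (0.75 + 2e-5 · elevation) · Ra`, `Ra` computed from
  latitude and day of year, and the relative-shortwave ratio capped at 1;
- wind speed defaults to the FAO-56 fallback of 2 m/s where a station
  does not record it.

A consequence worth knowing: with the shortwave ratio capped and the
longwave term negative at low radiation, daily Rn is strictly positive
for every non-negative solar radiation at the default site, so ET0 = 0
occurs only through the final non-negativity clip, not through a
constructible "zero net radiation" input.

Growing degree days use the clipped-average method: both daily extremes
are clipped into [Tbase, Tupper] = [8, 32] °C before averaging. The
canopy clock is calendar days, not thermal time, because the canopy
growth coefficient is specified per day; a GDD-driven canopy would need
a re-calibrated coefficient and is not provided.

## Soil water

The root zone is a single homogeneous bucket (clay loam defaults:
θ_SAT/θ_FC/θ_PWP = 0.50/0.39/0.23, 2.0 m deep, Ksat = 500 mm/day).
TAW = (θ_FC − θ_PWP)·1000 = 160 mm/m; the drainage coefficient comes
from the pedotransfer τ = 0.0866·Ksat^0.35 (0.76 for Ksat = 500),
clipped to (0, 1]. Daily update order: infiltrate rain + irrigation
(capped at saturation, excess shed as drainage), extract transpiration
down to the wilting point, percolate above-FC water at rate
τ·(storage − FC). Mass balance closes to numerical precision by
construction, which the suite audits over a year of random forcing.

The water-stress coefficient Ks is 1 until depletion exceeds
`p_upper · TAW` (default p_upper = 0.5, configurable — the depletion
threshold matters only for rain-fed scenario runs) and declines linearly
to 0 at full depletion. The `auto_fc` irrigation policy refills storage
to field capacity every day, which forces Ks = 1 throughout — the
stress-free regime under which the crop constants below were
calibrated. Soil evaporation, curve-number runoff, capillary rise and
salinity are not modelled; irrigation to field capacity makes the first
two largely moot and no data exist here to constrain the rest.

## Tea yield engine

Canopy cover grows from the post-pruning cover CCo = 20% as
`CC = CCo·e^(CGC·t)` until CC reaches CCx/2, then approaches the
maximum cover CCx = 95% as `CC = CCx − 0.25·(CCx²/CCo)·e^(−CGC·t)`
(continuous at the crossover by construction), with CGC = 0.007/day.
Transpiration is `Tr = Ks · (KsTr,x · KcTr) · ET0` with
`KcTr = KcTr,x · CC*`, `KcTr,x = 0.95`, and the micro-advection
adjustment `CC* = 1.72·CC − CC² + 0.30·CC³` (air moving over canopy
gaps makes transpiration per unit cover exceed the cover itself).
KsTr,x is a constant cold-stress multiplier, 1 by default; no cold
phenology submodel is attempted.

Biomass accrues through the climate-normalised water productivity:
`B = WP* · Σ Tr_i/ET0_i` with WP* = 18 g/m² (1 g/m² = 0.01 t/ha), and
yield is `Y = HI·B` with `HI = clip(multiplier·HIo, 14%, 19%)`,
HIo = 14%, multiplier 1 under no stress.

Two structural consequences:

- **Weather invariance under no stress.** With Ks = KsTr,x = 1,
  Tr/ET0 = KcTr exactly, so seasonal yield depends only on the canopy
  trajectory and season length, not on the weather year. Identical
  seasons across years are therefore the model's expected behaviour
  under full irrigation, not a bug.
- **WP*–HIo degeneracy.** Yield depends on WP* and HIo only through
  their product, so yield-only calibration cannot identify both. The
  default calibration grids (WP* 15–21 g/m² step 1, HIo 14–19% step 1%)
  contain no aliasing pair sharing the product 18 × 0.14, so the
  zero-noise round trip is exact; for noisy data the recommended
  procedure is the sequential one: fix HIo at its reference and
  calibrate WP*.

Each season is simulated independently from the post-pruning state;
no biomass carries over between seasons (tea is perennial, but the
harvested flush is regenerated each season and no carry-over rule can
be constrained by seasonal yield data). Calibration is an exhaustive
grid search minimising MAE/MSE/RMSE across seasons, with ties broken
deterministically toward the lexicographically smallest parameter
vector.

## Synthetic data generator

The generator emulates four growing seasons of a mountain tea station
(~34.47° N, 1000 m a.s.l.):

- **Weather**: seasonal sinusoids (temperatures peaking mid-July,
  humidity in the monsoon, radiation near the solstice) plus seeded
  Gaussian noise, mean-corrected so annual means match the four target
  years exactly; rainfall is a Bernoulli-occurrence / exponential-
  intensity process rescaled so each month's total matches a
  monsoon-peaked profile (July–August carry ~1/3 of the annual total).
  A fixed 15 °C mean tmin–tmax gap makes extreme-order violations
  negligible; any residual crossing is repaired by flooring tmin.
- **Plot samples**: the simulator runs once per season on the Apr 15 –
  Oct 15 plucking window (184 days; with the default parameters this
  gives 2.35 t/ha per season). Each of 4 one-acre plots gets a
  lognormal multiplicative effect (sd 10%, mean 1). The seasonal yield
  is split over 15 plucking dates in proportion to the biomass the
  simulator accrued in each inter-plucking window, jittered by a
  Dirichlet draw (concentration 150) around those shares — so a
  plucking's expected yield follows canopy development and the monsoon
  flush rather than being pure noise. Features are the weather
  aggregates of the window since the previous plucking (mean extremes
  and humidity, total rain); 5% multiplicative lognormal observation
  noise is applied last, and yields are stored in kg per one-acre plot.
  Defaults give 4 × 4 × 15 = 240 records, the size of the plot-level
  dataset the generator emulates.

What the generator does **not** emulate: spatial correlation between
plots, measurement gaps, plucking-calendar irregularity, green/black
processing differences (the tea-type indicator is carried but has no
yield effect by default), or any real relationship between weather
anomalies and seasonal totals (which the no-stress engine cannot
produce). Passing benchmark tests on these data therefore demonstrate
protocol correctness and the presence of a learnable nonlinear signal,
not predictive skill on real fields.

## Benchmark protocols

Features are [tmin, tmax, RHmean, rain, green-tea indicator]; the
target is yield in t/ha (1 kg/acre = 0.00247105 t/ha). Two protocols:
a seeded 70/30 train-test split and seeded 10-fold cross-validation
with unweighted averaging of per-fold MAE/MSE/RMSE (pooling across
held-out predictions is the other defensible choice; averaging was
chosen and is fixed). The split seed defaults to 42 and is recorded in
output metadata.

Eight regressors delegate to scikit-learn (LinearSVR, AdaBoost with a
decision-tree base, ARD, DecisionTree with max depth 20, MLP, MLR,
RANSAC, RBF-kernel SVR) and one to xgboost (colsample_bytree 0.4,
gamma 0, learning rate 0.1, max depth 20, min_child_weight 1.7, 100
estimators, reg_alpha 0.75, reg_lambda 0.45, subsample 0.8, seed 50,
single-threaded for bit reproducibility). SLR is a direct closed-form
one-predictor OLS on tmin, and a normal-equations MLR exists alongside
the delegated one as an independent cross-check. Hyperparameters not
listed use library defaults; no tuning is performed. MLP and LinearSVR
may not converge within their default iteration budgets on 240-row
tables; the fixed-budget fit is part of the protocol and warnings are
suppressed, not "fixed".

## Numerical choices and degenerate inputs

- All yields are t/ha internally; kg/acre is converted at ingestion.
- Canopy fractions live in [0, 1]; percentages are divided by 100 at
  the config boundary.
- `normalized_biomass` rejects Tr > 0 with ET0 = 0 (undefined ratio)
  and treats Tr = ET0 = 0 days as zero contribution.
- Grid calibration skips candidates whose simulation raises, and fails
  only if every candidate is infeasible.
- The sunset-hour-angle argument is clamped to [−1, 1] so polar sites
  do not produce domain errors.
- `simulate_season(..., cc_override=...)` pins the canopy at a constant
  fraction; it exists for analytic-limit checks (the constant-weather
  season then matches `HI · WP*·0.01 · n · KcTr,x · CC*(CCx)` exactly)
  and debugging, not production runs.

## Problem sizes

The bundled tests simulate 90–300-day seasons, calibrate over 4 seasons
on grids of ≤42 candidates, and benchmark 240-row tables; the full
pipeline (generate → simulate → calibrate → benchmark → compare) runs
in well under a minute on one CPU. These sizes were chosen as the
smallest at which every claimed property is exercised end to end.

## Known limitations

- No senescence phase: the default season is an evergreen pruned
  canopy; stage durations are configuration, not calibration.
- Yield-only calibration cannot separate WP* from HIo (see above), nor
  constrain CGC/CCo strongly when the season is long enough for the
  canopy to saturate.
- The benchmark's error magnitudes on synthetic data are not comparable
  to errors on real field data; only orderings and protocol behaviour
  are meaningful.
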