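# Methods

## Problem and model

Maize grain yield responds to plant density `d` (10⁴ plants ha⁻¹) as a
concave curve within the agronomically relevant range. Each multi-density
trial is summarized by an ordinary-least-squares quadratic

    Y(d) = a + b·d + c·d²,

whose vertex gives the trial's optimum plant density `OPD = −b/(2c)` and
the yield attained there, `Yield_OPD = a − b²/(4c)`. A trial contributes
a usable optimum only when the fit is concave (`c < 0`) and the vertex
lies inside an admissible window, by default
`[0.5·min(d), 1.2·max(d)]` — a guard against extrapolated vertices far
outside the densities actually evaluated. Non-concave or out-of-window
fits are kept in the record set flagged invalid (with the reason) and are
excluded from all downstream fitting; their count is logged. Replicated
densities participate in the least squares but count once toward the
screening threshold of ≥ 4 distinct levels. Trials under deficit water
supply are screened out, so the fitted optima describe well-watered,
adequately fertilized systems; the projections inherit that assumption.

Across trials, `Yield_OPD` is nearly linear in `OPD`; an OLS line
`Yield_OPD = α + β·OPD` (with the 95 % CI on β) converts projected
densities to attainable yields. Because the regressor `OPD` itself carries
estimation error from the quadratic fits, β is attenuated relative to the
generative slope (errors-in-variables); this bias is inherent to the
two-stage design and affects the real analysis in the same way.

## Growing-season predictors

Six predictors drive the density surrogate, aggregated over the inclusive
[sowing, maturity] window:

| predictor | aggregation | units |
|---|---|---|
| tmin_mean, tmax_mean | mean of daily Tmin / Tmax | °C |
| prec_sum | sum of daily precipitation | mm |
| radn_sum | sum of daily global radiation | MJ m⁻² |
| gdd_sum | sum of daily growing degree days | °C·d |
| som | topsoil (0–20 cm) organic matter | g kg⁻¹ |

Daily degree days clamp **both** Tmin and Tmax into [T_low, T_high] =
[10, 30] °C before averaging and subtracting T_low, so the daily value is
bounded in [0, 20] °C·d and is non-decreasing in either temperature.
Missing days inside the window are an error that lists the dates; an
opt-in linear interpolation handles gaps of at most 3 days (off by
default, since silent infilling can bias season sums). Where stations
record sunshine hours rather than radiation, the Angstrom–Prescott
relation `Rs = (a + b·n/N)·Ra` is applied with FAO-56 extraterrestrial
radiation `Ra` and daylength `N`; the coefficients default to the FAO-56
recommendations a = 0.25, b = 0.50 and can be overridden per station when
a local calibration exists. Soil organic carbon converts to organic
matter by the van Bemmelen factor 1.724, unit-preserving, and only when a
SOM column is absent.

## The density surrogate

A random-forest regression maps the six predictors to trial OPD:
500 trees, 3 candidate predictors per split, fixed seed (default 42,
recorded in every report); scikit-learn's `RandomForestRegressor` is the
backend. Skill is reported on a random 80/20 holdout and, as a stricter
check, by leave-one-out refitting. Metrics: R² is the squared Pearson
correlation of observed and simulated values; RMSE the root mean squared
error; RRMSE = RMSE / mean(observed) × 100 %. R² centres the simulated
values on their own mean; a variant that centres them on the observed
mean instead is available behind `as_printed=True` for auditing analyses
that used that form. R² and RRMSE are flagged undefined (NaN) for
zero-variance predictions or a zero observed mean rather than silently
reported.

Driver attribution uses permutation importance: the increase in MSE when
one predictor's column is shuffled, averaged over 10 shuffles, computed
within each region, floored at zero and rescaled to sum to 100 % per
region (regions with fewer than 10 records are skipped with a warning).
Permutation importance is unsigned, so each driver's sign and
significance come from the univariate within-region OLS slope of OPD on
that driver (two-sided t-test). Driver–response shapes are fitted as
linear vs quadratic curves selected by adjusted R², reporting the
derivative at the data mean as the per-unit effect. The SOM plateau is
located by hinge regression: OPD is regressed on the five climate
predictors plus `min(SOM, k)` over a grid of candidate knots
k ∈ [8, 32] g kg⁻¹ (0.25 steps), choosing k by minimum residual sum of
squares. Adjusting for the climate predictors matters: they absorb most
non-SOM variance and sharpen the knot profile considerably compared to a
marginal SOM fit.

## Scenario projections

Stations carry farmer practice (planting density and yield), soil, fixed
sowing/maturity dates, and daily weather. For every scenario, season
predictors are computed **per year**, the surrogate predicts OPD per
year, and predictions are averaged within each 10-year decade (2010s =
2010–2019, 2030s = 2030–2039). The alternative — averaging climate first
and predicting once — is available behind `average_climate_first` but is
not the default, since the forest is nonlinear and the yearly route
represents interannual variability. Growing-season windows are held at
their observed dates in future decades; no phenology-shift model is
applied.

The soil-improvement scenario replaces station SOM by
`max(SOM, 20 g kg⁻¹)` — soils are raised to the management threshold,
never lowered. Density gap = OPD − farmer density; yield gap = attainable
yield − farmer yield; attainment = farmer density / OPD; percent yield
improvement = yield gap / farmer yield × 100 (undefined at zero farmer
yield, flagged).

Ensemble accounting: per GCM member, regional and national means are
formed first; percent changes are computed per member against that
member's own 2010s baseline and only then summarized across members
(mean, median, 10/25/75/90th percentiles with linear interpolation
between order statistics, numpy's default). Computing the change of
ensemble means instead would mix member baselines; a regression test pins
the per-member-first convention. All members carry equal weight. A
single-member "ensemble" yields degenerate percentiles and is flagged.
Historical national density and yield trends are OLS lines through ≥ 5
annual points, extrapolated to the target year, with the slope also
reported per decade.

## Demand and supply accounting

Apparent national demand (Mt) = production + imports − exports − stock
change (ending minus beginning stocks), averaged over the baseline years
before dividing by the baseline population to get per-capita demand
(kg person⁻¹ yr⁻¹). Demand at the target year holds per-capita use
constant at the projected population. Supply = Σ regional harvested area
× scenario yield / 10⁶ (Mg → Mt). The self-sufficiency ratio is
production / demand, with ≥ 1 read as demand fully met domestically. All
masses are fixed at Mt internally and per-capita values at kg; the
baseline supply-utilization figures are user-supplied configuration
(the defaults are calibrated so that the baseline reproduces the reported
national totals: ≈ 290.8 Mt apparent demand for 1.428 × 10⁹ people,
hence ≈ 292 Mt at the 2035 population of 1.434 × 10⁹).

## The synthetic-data generator

The generator supplies the study conditions end to end: 448 trial-level
(OPD, Yield_OPD) pairs, 402 stations in four regions (NE coolest, SW
wettest), and a 22-member pseudo-GCM ensemble covering the 2010s and
2030s. A known additive truth surface defines the generative optimum:

    OPD* = 4.05 − 0.18·tmin_mean − 0.02·tmax_mean + 0.0004·prec_sum
           + 0.0016·radn_sum + 0.0001·gdd_sum + 0.16·min(som, 20),

clipped to [4, 12] ×10⁴ plants ha⁻¹, with
`Yield_OPD* = 2.1 + 1.2·OPD*`. The single hinge in SOM is the simplest
form consistent with a fertility response that saturates near
20 g kg⁻¹; the temperature coefficient sits inside the empirically
reported 0.16–0.51 ×10⁴ plants ha⁻¹ per °C range and the radiation
coefficient inside 1–2 ×10⁴ plants ha⁻¹ per 1000 MJ m⁻². Regional
climatologies are chosen so the national mean truth OPD is ≈ 7.8 ×10⁴
plants ha⁻¹ with regional means between ≈ 7.0 (SW) and ≈ 8.8 (NW).
Farmer densities are drawn 15–30 % below the station optimum
(≈ 77 % attainment) and farmer yields at 48–56 % of the attainable yield
(≈ 6 vs ≈ 11.5 Mg ha⁻¹).

Daily weather is a centred seasonal sine course plus AR(1) noise
(ρ = 0.7, innovation sd 1.8 °C) on temperatures, clipped Gaussian
radiation, and Bernoulli-exponential precipitation with region-specific
wet-day probability; station-level offsets create persistent spatial
variation. Trials sample unique site-years (1–3 hybrids each sharing the
site-year weather, as in a site × year × hybrid design), draw 4–6 density
levels spanning the truth optimum, and add homoscedastic Gaussian noise
(sd 0.3 Mg ha⁻¹) to quadratic yields whose vertex is the truth optimum
plus a small hybrid effect (sd 0.15). Each pseudo-GCM member draws a
warming delta (mean +0.8 °C reached by the 2030s, sd 0.3 across members —
a realistic near-term high-forcing trajectory) and a precipitation
scaling, then reuses one stochastic decade block of weather in every
decade with the trend ramped on top, so decade contrasts isolate the
imposed trend exactly: a zero-delta member reproduces its 2010s in the
2030s bit for bit. All generators are reproducible children of a single
seed sequence.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: no spatial correlation of weather between
stations; no phenology response to warming; no genotype × environment
interaction beyond a random hybrid offset; yields from an exact quadratic
rather than a crop model; no drought, lodging, pest or nutrient
limitation; regional mean optima follow the additive surface, so their
ordering does not reproduce every regional contrast a real compiled
dataset shows (NE and NCP are interchanged relative to the emulated
study region means). The surrogate's holdout skill on synthetic data
(R² ≈ 0.8, RRMSE ≈ 5 %) is accordingly better than is realistic for
literature-compiled observations.

## Numerical choices and edge cases

- Quadratic and driver-curve fits use `numpy.linalg.lstsq`; exact
  collinearity (fewer than 3 distinct densities; zero driver variance)
  raises a degenerate-design error rather than returning garbage.
- The 80/20 split rounds the train size to the nearest integer, keeps it
  within [1, n−1], refuses n < 5, and is a seeded permutation: disjoint
  and exhaustive by construction.
- Permutation-importance negatives are floored at zero before
  normalization; if every floored importance is zero the weights fall
  back to uniform.
- Random-forest training requires ≥ 30 rows; leave-one-out ≥ 10.
- Decade projection validates that every station has all 10 years of
  every requested decade and names the offending member otherwise.
- Percentiles use linear interpolation between order statistics.
- The gap identity `Yield_OPD − yield gap = farmer yield` holds to
  floating-point round-off (the gap is computed by subtraction).
- The pipeline halts at the first failing stage, names it in the run
  report, and leaves partial artifacts on disk; reports embed the config
  hash, seed and package version.

## Problem sizes

Unit tests run on reduced configurations (typically 120 trials,
60 stations, 2–4 ensemble members, 100 trees) chosen to exercise every
code path; the acceptance checks and `scripts/acceptance.py` run the full
configuration (448 trials, 402 stations, 22 members, 500 trees), which
completes in well under a minute on one CPU.
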