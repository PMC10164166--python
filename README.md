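# opdcast

Optimum maize plant density (OPD) estimation, mapping and projection from
multi-density yield trials and station agro-climate data.

Maize yield responds to planting density as a concave curve: too sparse
wastes light and land, too dense provokes competition and lodging. The
density that maximizes grain yield — the OPD — shifts with growing-season
climate and soil fertility, so a single recommended density cannot serve a
large, diverse cropping area. `opdcast` implements a full analysis chain
for this problem, aimed at agronomists and crop modellers:

1. **Trial curves** — screen multi-density field trials (adequate water
   supply, ≥ 4 distinct density levels), fit the quadratic response
   `Y = a + b·d + c·d²` per trial, and take the vertex
   `OPD = −b/2c`, `Yield_OPD = a − b²/4c` as the trial's optimum. A linear
   relation `Yield_OPD = α + β·OPD` across trials maps projected densities
   to attainable yields.
2. **Agro-climate features** — growing-season predictors per trial or
   station: mean daily Tmin and Tmax, summed precipitation, summed solar
   radiation (from sunshine hours via the Angstrom–Prescott equation when
   radiation is not observed), summed growing degree days
   `GDD = (T*min + T*max)/2 − 10` with both temperatures clamped to
   [10, 30] °C, and topsoil organic matter (SOM = SOC × 1.724).
3. **Density surrogate** — a random-forest regression of trial OPD on the
   six predictors (500 trees, 3 candidate predictors per split), evaluated
   by random 80/20 holdout and leave-one-out (R², RMSE, RRMSE), with
   permutation importance scaled to sum to 100% per region and simple
   driver-response curves (including the SOM plateau near 20 g kg⁻¹,
   beyond which extra organic matter no longer raises the optimum).
4. **Scenarios** — station-level OPD and attainable yield under the
   observed decade (2010s) and a 22-member GCM ensemble for the 2030s,
   with or without raising SOM to the 20 g kg⁻¹ management threshold;
   density and yield gaps against farmer practice; per-member percent
   changes summarized by ensemble percentiles; historical-trend
   extrapolation of national density and yield.
5. **Sufficiency** — national maize demand (production + imports − exports
   − stock change, per-capita held constant to a target population) versus
   projected production from current harvested area at the scenario yield.

A synthetic-data module generates trials, stations, daily weather and
pseudo-GCM ensembles from a known ground-truth density surface, so every
stage of the pipeline is testable end to end — including whether the
analysis recovers the generative effect signs, the SOM plateau location
and station-level optima.

## Worked example

```python
from opdcast import (
    SynthConfig, generate_stations, generate_trials,
    screen_trials, fit_yield_density_curve, extract_optimum,
    default_density_window, fit_opd_yield_relation,
    build_feature_matrix, split_train_eval, train_opd_model,
    evaluate_predictions,
)
from opdcast.pipeline import attach_trial_predictors
from opdcast.agroclimate import GddParams

synth = generate_stations(SynthConfig(n_trials=200, n_stations=100, seed=42))
trials, _, weather = generate_trials(synth)
attach_trial_predictors(trials, weather, GddParams())

records = [
    extract_optimum(fit_yield_density_curve(t), default_density_window(t.densities),
                    trial_id=t.trial_id, predictors=t.predictors, region=t.region)
    for t in screen_trials(trials, min_levels=4)
]
relation = fit_opd_yield_relation(records)
print(f"valid trials: {sum(r.valid for r in records)} / {len(records)}")
print(f"Yield_OPD = {relation.alpha:.2f} + {relation.beta:.2f}·OPD  (r² = {relation.r2:.2f})")

data = build_feature_matrix(records)
train, test = split_train_eval(data, fraction=0.8, seed=42)
model = train_opd_model(train, n_trees=500, m_try=3, seed=42)
report = evaluate_predictions(test["opd"].to_numpy(), model.predict(test))
print(f"holdout: R² = {report.r2:.2f}, RMSE = {report.rmse:.2f} ×10⁴ plants/ha, "
      f"RRMSE = {report.rrmse:.1f}%")
```

prints

```
valid trials: 200 / 200
Yield_OPD = 3.42 + 1.03·OPD  (r² = 0.80)
holdout: R² = 0.70, RMSE = 0.43 ×10⁴ plants/ha, RRMSE = 5.5%
```

Every trial here yields a usable optimum (concave fit with the vertex
inside the admissible density window); the attainable yield rises about
1 Mg ha⁻¹ per 10⁴ plants ha⁻¹ of extra optimal density; and the surrogate
predicts held-out trial optima to within ±0.43 ×10⁴ plants ha⁻¹ (≈ 5%
of the mean).

## Command line

```bash
opdcast run-all --config config.yaml --seed 42 --out workspace/
```

or stage by stage: `simulate`, `fit-curves`, `train`, `evaluate`,
`project`, `scenario`, `sufficiency`, `report` — each reads the previous
stage's CSV artifacts from the workspace. See `opdcast --help`.

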