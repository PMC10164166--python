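"""End-to-end run: trials → curves → surrogate → projections → verdict.

``run_pipeline`` executes the stages in order — screen, fit curves,
build features, train, evaluate, interrogate drivers, project stations
under current and future climate (with and without soil improvement),
compute gaps, extrapolate historical trends, and close with the national
demand/supply verdict — writing tidy CSV/JSON artifacts and a
machine-readable run report (config hash, seed, per-stage status).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .agroclimate import GddParams, season_predictors
from .trial_curves import (
    default_density_window,
    extract_optimum,
    fit_opd_yield_relation,
    fit_yield_density_curve,
    screen_trials,
)
from .opd_model import (
    build_feature_matrix,
    estimate_som_plateau,
    evaluate_predictions,
    loo_evaluate,
    partial_response,
    split_train_eval,
    train_opd_model,
    variable_importance,
)
from .scenarios import (
    ScenarioSpec,
    compute_gaps,
    extrapolate_trend,
    project_decades,
    project_decades_multi,
    summarize_ensemble,
)
from .sufficiency import (
    DemandSpec,
    assess_sufficiency,
    baseline_per_capita_demand,
    project_demand,
    supply_from_area_yield,
)
from .io import PipelineConfig, records_to_frame, write_stations, write_trials
from . import synth as synthmod

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "summarize_field_trials", "attach_trial_predictors"]


@dataclass
class RunReport:
    """Provenance record of one pipeline run."""

    seed: int
    config_hash: str
    version: str = __version__
    stages: dict = field(default_factory=dict)        # stage → "ok" / error text
    counts: dict = field(default_factory=dict)        # rows kept/dropped per stage
    metrics: dict = field(default_factory=dict)       # headline numbers
    outputs: dict = field(default_factory=dict)       # artifact paths

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))

    @property
    def ok(self) -> bool:
        return all(v == "ok" for v in self.stages.values())


def attach_trial_predictors(trials, weather: pd.DataFrame, gdd_params: GddParams) -> None:
    """Compute each trial's growing-season predictors from daily weather."""
    by_site = {sid: grp for sid, grp in weather.groupby("station_id", sort=False)}
    for t in trials:
        site = by_site.get(t.site_id)
        if site is None:
            raise ValueError(f"no weather for trial {t.trial_id} site {t.site_id}")
        t.predictors = season_predictors(
            site, (t.sowing, t.maturity), t.som, gdd_params
        )


def summarize_field_trials(pairs: pd.DataFrame) -> pd.DataFrame:
    """Regional and national control vs optimum-treatment comparison.

    Expects one row per site with ck_density, ck_yield, ot_density,
    ot_yield; rows with missing values (unpaired sites) are excluded with
    a warning. National means are unweighted site means. The percent
    yield improvement compares group-mean optimum to group-mean control.
    """
    value_cols = ["ck_density", "ck_yield", "ot_density", "ot_yield"]
    missing = pairs[value_cols].isna().any(axis=1)
    if missing.any():
        logger.warning("excluding %d unpaired site(s)", int(missing.sum()))
        pairs = pairs[~missing]
    national = pairs.copy()
    national["region"] = "ALL"
    rows = []
    for region, grp in pd.concat([pairs, national]).groupby("region"):
        row = dict(region=region, n_sites=len(grp))
        for col in value_cols:
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_se"] = float(grp[col].std(ddof=1) / np.sqrt(len(grp)))
        row["yield_improvement_pct"] = (
            (row["ot_yield_mean"] / row["ck_yield_mean"] - 1.0) * 100.0
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _stage(report: RunReport, name: str):
    """Record stage status; re-raise with the stage named."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s ...", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                report.stages[name] = "ok"
                logger.info("stage %s done (%.1f s)", name, time.time() - self.t0)
                return False
            report.stages[name] = f"failed: {exc}"
            logger.error("stage %s failed: %s", name, exc)
            return False

    return _Ctx()


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    outdir: Optional[str | Path] = None,
    write_artifacts: bool = True,
) -> tuple[RunReport, dict]:
    """Execute the full analysis on synthetic data.

    Returns the run report and a dict of in-memory result objects
    (records, model, result frames). Any stage error halts the run; the
    report names the failed stage and partial artifacts stay on disk.
    """
    report = RunReport(seed=config.seed, config_hash=config.config_hash())
    out = Path(outdir or config.outdir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    res: dict = {}
    gdd_params = GddParams(config.gdd_t_low, config.gdd_t_high)

    try:
        with _stage(report, "generate"):
            scfg = synthmod.SynthConfig(seed=config.seed, **(config.synth or {}))
            surface = synthmod.TruthSurface()
            stations = synthmod.generate_stations(scfg, surface)
            trials, trial_truth, trial_weather = synthmod.generate_trials(stations)
            res.update(synth=stations, trials=trials, trial_truth=trial_truth,
                       trial_weather=trial_weather, synth_config=scfg)
            report.counts["trials_generated"] = len(trials)
            report.counts["stations"] = len(stations.stations)
            if write_artifacts:
                write_trials(trials, out / "trials.csv")
                write_stations(stations.stations, out / "stations.csv")
                synthmod.write_truth(stations, trial_truth, out / "truth.json")

        with _stage(report, "screen_and_fit_curves"):
            attach_trial_predictors(trials, trial_weather, gdd_params)
            kept = screen_trials(trials, config.min_levels)
            records = []
            for t in kept:
                fit = fit_yield_density_curve(t)
                rec = extract_optimum(
                    fit, default_density_window(t.densities),
                    trial_id=t.trial_id, predictors=t.predictors, region=t.region,
                )
                records.append(rec)
            n_valid = sum(r.valid for r in records)
            report.counts.update(
                trials_screened=len(kept), records_valid=n_valid,
                records_invalid=len(records) - n_valid,
            )
            res["records"] = records
            if write_artifacts:
                records_to_frame(records).to_csv(out / "opd_records.csv", index=False)

        with _stage(report, "linear_yield_relation"):
            yield_model = fit_opd_yield_relation(records)
            res["yield_model"] = yield_model
            report.metrics["yield_relation"] = dict(
                alpha=yield_model.alpha, beta=yield_model.beta,
                r2=yield_model.r2, ci95=yield_model.ci95,
            )

        with _stage(report, "train_and_evaluate"):
            data = build_feature_matrix(records)
            res["features"] = data
            train, test = split_train_eval(data, 0.8, config.seed)
            model = train_opd_model(train, config.n_trees, config.m_try, config.seed)
            holdout = evaluate_predictions(
                test["opd"].to_numpy(), model.predict(test)
            )
            res["model"] = model
            res["holdout"] = holdout
            report.metrics["holdout"] = dataclasses.asdict(holdout)
            if config.run_loo:
                loo = loo_evaluate(data, config.n_trees, config.m_try, config.seed)
                res["loo"] = loo
                report.metrics["loo"] = dataclasses.asdict(loo)
            # the production model is refit on all records
            model_full = train_opd_model(data, config.n_trees, config.m_try, config.seed)
            res["model_full"] = model_full
            if write_artifacts:
                model_full.save(out / "model.joblib")
                (out / "eval.json").write_text(json.dumps(report.metrics, indent=1))

        with _stage(report, "drivers"):
            importance = variable_importance(
                res["model_full"], data, seed=config.seed
            )
            res["importance"] = importance
            responses = {
                drv: dataclasses.asdict(partial_response(data, drv))
                for drv in ("tmin_mean", "radn_sum", "som")
            }
            knot, slope_below = estimate_som_plateau(data)
            res["som_plateau"] = (knot, slope_below)
            report.metrics["som_plateau_g_kg"] = knot
            res["responses"] = responses
            if write_artifacts:
                importance.to_csv(out / "importance.csv", index=False)
                (out / "partial_responses.json").write_text(json.dumps(responses, indent=1))

        with _stage(report, "project_current"):
            spec_cur = ScenarioSpec(
                "current", climate="current", decades=(tuple(config.decades[0]),)
            )
            current = project_decades(
                res["model_full"], yield_model, stations.stations,
                [("observed", stations.daily)], spec_cur, gdd_params,
            )
            res["current"] = current
            gaps = compute_gaps(current, stations.stations)
            res["gaps"] = gaps
            report.metrics["national"] = dict(
                opd=float(current["opd"].mean()),
                yield_opd=float(current["yield_opd"].mean()),
                density_gap=float(gaps["density_gap"].mean()),
                yield_gap=float(gaps["yield_gap"].mean()),
                attainment_pct=float(gaps["attainment"].mean() * 100.0),
                yield_improvement_pct=float(
                    gaps["yield_gap"].mean() / gaps["farmer_yield"].mean() * 100.0
                ),
            )
            if write_artifacts:
                current.to_csv(out / "station_opd.csv", index=False)
                gaps.to_csv(out / "gaps.csv", index=False)

        with _stage(report, "project_scenarios"):
            decades = tuple(tuple(d) for d in config.decades)
            specs = [
                ScenarioSpec("climate", som_threshold=None, decades=decades),
                ScenarioSpec("climate+som", som_threshold=config.som_threshold,
                             decades=decades),
            ]
            gcms = synthmod.generate_future_climate(stations, decades=decades)
            scen = project_decades_multi(
                res["model_full"], yield_model, stations.stations, gcms, specs, gdd_params
            )
            res["scenarios"] = scen
            summary = summarize_ensemble(scen)
            res["ensemble_summary"] = summary
            nat = summary[(summary["region"] == "ALL") & (summary["variable"] == "opd")]
            fut = f"{config.decades[-1][0]}s"
            report.metrics["scenario_opd_pct_change"] = {
                s: float(
                    nat[(nat["scenario"] == s) & (nat["decade"] == fut)]["pct_change_mean"].iloc[0]
                )
                for s in ("climate", "climate+som")
            }
            # soil-improvement effect: climate+som vs climate at the same decade
            som_eff = {}
            for dec_label in (f"{config.decades[0][0]}s", fut):
                m = {
                    s: float(nat[(nat["scenario"] == s) & (nat["decade"] == dec_label)]["mean"].iloc[0])
                    for s in ("climate", "climate+som")
                }
                som_eff[dec_label] = (m["climate+som"] / m["climate"] - 1.0) * 100.0
            report.metrics["som_improvement_opd_pct"] = som_eff
            if write_artifacts:
                scen.to_csv(out / "scenario_results.csv", index=False)
                summary.to_csv(out / "ensemble_summary.csv", index=False)

        with _stage(report, "historical_trend"):
            history = synthmod.generate_national_history(res["synth_config"])
            dens_trend, dens_2035 = extrapolate_trend(
                history["year"], history["density"], config.trend_target_year
            )
            yld_trend, yld_2035 = extrapolate_trend(
                history["year"], history["yield_mg_ha"], config.trend_target_year
            )
            res["history"] = history
            report.metrics["trend"] = dict(
                density_slope_per_decade=dens_trend.slope_per_decade,
                density_2035=dens_2035,
                yield_slope_per_decade=yld_trend.slope_per_decade,
                yield_2035=yld_2035,
            )

        with _stage(report, "sufficiency"):
            spec = DemandSpec(**config.demand)
            demand_base, per_capita = baseline_per_capita_demand(spec)
            demand_target = project_demand(per_capita, spec.population_target)
            # projected supply: harvested area held constant, yields from
            # the climate+SOM scenario in the future decade, per region
            summary = res["ensemble_summary"]
            fut = f"{config.decades[-1][0]}s"
            yld = summary[
                (summary["scenario"] == "climate+som")
                & (summary["decade"] == fut)
                & (summary["variable"] == "yield_opd")
            ].set_index("region")["mean"]
            supply = supply_from_area_yield(
                config.area_ha, {r: float(yld[r]) for r in config.area_ha}
            )
            verdict = assess_sufficiency(supply.production_mt, demand_target)
            res["verdict"] = verdict
            report.metrics["sufficiency"] = dict(
                per_capita_kg=per_capita, demand_baseline_mt=demand_base,
                demand_target_mt=demand_target, production_mt=supply.production_mt,
                ratio=verdict.ratio, self_sufficient=verdict.self_sufficient,
            )
            if write_artifacts:
                (out / "sufficiency.json").write_text(
                    json.dumps(report.metrics["sufficiency"], indent=1)
                )

        with _stage(report, "field_trial_comparison"):
            pairs = synthmod.generate_field_trials(stations)
            comparison = summarize_field_trials(pairs)
            res["field_comparison"] = comparison
            nat_row = comparison[comparison["region"] == "ALL"].iloc[0]
            report.metrics["field_trials"] = dict(
                ot_density=float(nat_row["ot_density_mean"]),
                ot_yield=float(nat_row["ot_yield_mean"]),
                yield_improvement_pct=float(nat_row["yield_improvement_pct"]),
            )
            if write_artifacts:
                comparison.to_csv(out / "field_trial_comparison.csv", index=False)
    finally:
        if write_artifacts:
            report.to_json(out / "report.json")

    if not report.ok:
        failed = [k for k, v in report.stages.items() if v != "ok"]
        raise RuntimeError(f"pipeline halted at stage {failed[0]}: {report.stages[failed[0]]}")
    return report, res
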