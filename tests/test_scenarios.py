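"""Station projection, gap accounting, ensembles and trend extrapolation."""

import numpy as np
import pandas as pd
import pytest

from opdcast.opd_model import train_opd_model
from opdcast.scenarios import (
    ScenarioSpec,
    apply_som_improvement,
    compute_gaps,
    extrapolate_trend,
    predict_station_optima,
    project_decades,
    project_decades_multi,
    summarize_ensemble,
)
from opdcast.synth import SynthConfig, generate_future_climate, generate_stations
from opdcast.trial_curves import LinearYieldModel

YM = LinearYieldModel(alpha=2.1, beta=1.2, r2=0.9, ci95=0.05, n=100)


@pytest.fixture(scope="module")
def toy_model(rng_module=np.random.default_rng(5)):
    """RF fitted on a smooth surface over station-like features."""
    n = 300
    data = pd.DataFrame(
        dict(
            tmin_mean=rng_module.uniform(13, 21, n),
            tmax_mean=rng_module.uniform(24, 31, n),
            prec_sum=rng_module.uniform(200, 900, n),
            radn_sum=rng_module.uniform(1900, 3300, n),
            gdd_sum=rng_module.uniform(1400, 2200, n),
            som=rng_module.uniform(5, 35, n),
        )
    )
    data["opd"] = (
        4.0 - 0.18 * data["tmin_mean"] + 0.0016 * data["radn_sum"]
        + 0.16 * np.minimum(data["som"], 20.0)
    )
    return train_opd_model(data, n_trees=100, seed=0), data


class TestPredictStations:
    def test_training_row_interpolates_into_target_range(self, toy_model):
        model, data = toy_model
        stations = data.head(20).copy()
        stations.insert(0, "station_id", [f"S{i}" for i in range(20)])
        out = predict_station_optima(model, YM, stations)
        assert out["opd"].between(data["opd"].min(), data["opd"].max()).all()

    def test_yield_monotone_in_opd(self, toy_model):
        model, data = toy_model
        stations = data.head(30).copy()
        stations.insert(0, "station_id", [f"S{i}" for i in range(30)])
        out = predict_station_optima(model, YM, stations).sort_values("opd")
        assert out["yield_opd"].is_monotonic_increasing

    def test_national_mean_is_per_station_average(self, toy_model):
        model, data = toy_model
        stations = data.head(50).copy()
        stations.insert(0, "station_id", [f"S{i}" for i in range(50)])
        out = predict_station_optima(model, YM, stations)
        brute = sum(out["opd"]) / len(out)  # explicit loop-style aggregation
        assert out["opd"].mean() == pytest.approx(brute, rel=1e-12)


class TestGaps:
    def _stations(self):
        return pd.DataFrame(
            dict(station_id=["A", "B"], farmer_density=[6.1, 7.0], farmer_yield=[6.0, 0.0])
        )

    def _results(self):
        return pd.DataFrame(
            dict(station_id=["A", "B"], opd=[7.8, 7.0], yield_opd=[11.7, 9.0])
        )

    def test_gap_arithmetic(self):
        gaps = compute_gaps(self._results(), self._stations())
        a = gaps[gaps["station_id"] == "A"].iloc[0]
        assert a["density_gap"] == pytest.approx(1.7)
        assert a["yield_gap"] == pytest.approx(5.7)
        assert a["yield_improvement_pct"] == pytest.approx(95.0)

    def test_zero_farmer_yield_flagged(self):
        gaps = compute_gaps(self._results(), self._stations())
        b = gaps[gaps["station_id"] == "B"].iloc[0]
        assert np.isnan(b["yield_improvement_pct"])

    def test_farmer_at_optimum_has_zero_gaps(self):
        res = pd.DataFrame(dict(station_id=["A"], opd=[6.1], yield_opd=[6.0]))
        gaps = compute_gaps(res, self._stations())
        assert gaps["density_gap"].iloc[0] == pytest.approx(0.0)
        assert gaps["yield_gap"].iloc[0] == pytest.approx(0.0)

    def test_gap_identity(self, rng):
        stations = pd.DataFrame(
            dict(
                station_id=[f"S{i}" for i in range(50)],
                farmer_density=rng.uniform(5, 7, 50),
                farmer_yield=rng.uniform(4, 8, 50),
            )
        )
        results = pd.DataFrame(
            dict(
                station_id=stations["station_id"],
                opd=rng.uniform(7, 9, 50),
                yield_opd=rng.uniform(10, 13, 50),
            )
        )
        gaps = compute_gaps(results, stations)
        resid = (gaps["yield_opd"] - gaps["yield_gap"]) - gaps["farmer_yield"]
        assert np.abs(resid).max() <= 1e-12 * gaps["yield_opd"].abs().max()


class TestSomImprovement:
    @pytest.mark.parametrize("som, expected", [(15.0, 20.0), (25.0, 25.0), (20.0, 20.0)])
    def test_threshold_rule(self, som, expected):
        assert apply_som_improvement(som, 20.0) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_som_improvement(15.0, -1.0)

    def test_never_decreases(self, rng):
        som = rng.uniform(0, 40, 200)
        assert (apply_som_improvement(som, 20.0) >= som).all()


@pytest.fixture(scope="module")
def tiny_world():
    """Small station set + fitted surrogate for projection tests."""
    cfg = SynthConfig(n_trials=40, n_stations=24, n_gcms=3, seed=11)
    synth = generate_stations(cfg)
    rng = np.random.default_rng(0)
    n = 200
    data = pd.DataFrame(
        dict(
            tmin_mean=rng.uniform(12, 22, n),
            tmax_mean=rng.uniform(23, 32, n),
            prec_sum=rng.uniform(150, 1000, n),
            radn_sum=rng.uniform(1800, 3400, n),
            gdd_sum=rng.uniform(1300, 2400, n),
            som=rng.uniform(5, 35, n),
        )
    )
    data["opd"] = (
        4.0 - 0.18 * data["tmin_mean"] + 0.0016 * data["radn_sum"]
        + 0.16 * np.minimum(data["som"], 20.0)
    )
    model = train_opd_model(data, n_trees=100, seed=0)
    return cfg, synth, model


class TestProjectDecades:
    def test_zero_warming_means_identical_decades(self, tiny_world):
        cfg, synth, model = tiny_world
        frozen = SynthConfig(
            n_trials=cfg.n_trials, n_stations=cfg.n_stations, n_gcms=2, seed=cfg.seed,
            warming_delta_mean=0.0, warming_delta_sd=0.0, prec_scale_sd=0.0,
        )
        spec = ScenarioSpec("frozen")
        out = project_decades(
            model, YM, synth.stations,
            generate_future_climate(synth, frozen), spec,
        )
        wide = out.pivot_table(index=["station_id", "gcm_id"], columns="decade", values="opd")
        assert np.allclose(wide["2010s"], wide["2030s"], atol=1e-12)

    def test_warming_lowers_density(self, tiny_world):
        cfg, synth, model = tiny_world
        warm = SynthConfig(
            n_trials=cfg.n_trials, n_stations=cfg.n_stations, n_gcms=3, seed=cfg.seed,
            warming_delta_mean=2.0, warming_delta_sd=0.1,
        )
        out = project_decades(
            model, YM, synth.stations,
            generate_future_climate(synth, warm), ScenarioSpec("warm"),
        )
        dec = out.groupby("decade")["opd"].mean()
        assert dec["2030s"] < dec["2010s"]

    def test_decade_mean_equals_per_year_loop(self, tiny_world):
        cfg, synth, model = tiny_world
        gcms = list(generate_future_climate(synth, decades=((2010, 2019),)))
        out = project_decades(
            model, YM, synth.stations, gcms,
            ScenarioSpec("chk", decades=((2010, 2019),)),
        )
        gcm_id, daily = gcms[0]
        som = synth.stations.set_index("station_id")["som"]
        sid = synth.stations["station_id"].iloc[0]
        from opdcast.agroclimate import aggregate_seasons

        feats = aggregate_seasons(daily[daily["station_id"] == sid])
        feats["som"] = som[sid]
        per_year = model.predict(feats)
        expect = per_year.mean()
        got = out[(out["station_id"] == sid) & (out["gcm_id"] == gcm_id)]["opd"].iloc[0]
        assert got == pytest.approx(expect, rel=1e-12)

    def test_decade_aggregation_permutation_invariant(self, tiny_world):
        cfg, synth, model = tiny_world
        gcms = list(generate_future_climate(synth, decades=((2010, 2019),)))
        spec = ScenarioSpec("perm", decades=((2010, 2019),))
        out1 = project_decades(model, YM, synth.stations, gcms, spec)
        shuffled = [(g, d.sample(frac=1.0, random_state=1)) for g, d in gcms]
        out2 = project_decades(model, YM, synth.stations, shuffled, spec)
        m1 = out1.set_index(["station_id", "gcm_id"])["opd"].sort_index()
        m2 = out2.set_index(["station_id", "gcm_id"])["opd"].sort_index()
        assert np.allclose(m1, m2, atol=1e-12)

    def test_som_scenario_uses_raised_som(self, tiny_world):
        cfg, synth, model = tiny_world
        gcms = list(generate_future_climate(synth, decades=((2010, 2019),)))
        specs = [
            ScenarioSpec("plain", decades=((2010, 2019),)),
            ScenarioSpec("som20", som_threshold=20.0, decades=((2010, 2019),)),
        ]
        out = project_decades_multi(model, YM, synth.stations, gcms, specs)
        mean = out.groupby("scenario")["opd"].mean()
        assert mean["som20"] > mean["plain"]  # monotone truth surface

    def test_missing_years_error_names_gcm(self, tiny_world):
        cfg, synth, model = tiny_world
        gcms = list(generate_future_climate(synth, decades=((2010, 2019),)))
        gcm_id, daily = gcms[0]
        truncated = daily[daily["year"] != 2015]
        with pytest.raises(ValueError, match=gcm_id):
            project_decades(
                model, YM, synth.stations, [(gcm_id, truncated)],
                ScenarioSpec("bad", decades=((2010, 2019),)),
            )


class TestEnsembleSummary:
    def _results(self, values_by_member, decade="2030s"):
        rows = []
        for gcm, v in values_by_member.items():
            for dec, val in (("2010s", 1.0 * v), (decade, v * 1.1)):
                rows.append(
                    dict(station_id="A", gcm_id=gcm, decade=dec,
                         scenario="s", opd=val, yield_opd=val)
                )
        return pd.DataFrame(rows)

    def test_identical_members_degenerate_percentiles(self):
        res = self._results({f"G{i}": 8.0 for i in range(5)})
        summary = summarize_ensemble(res)
        row = summary[(summary["decade"] == "2030s") & (summary["variable"] == "opd")].iloc[0]
        assert row["p10"] == row["p25"] == row["median"] == row["p75"] == row["p90"] == row["mean"]

    def test_percentiles_match_order_statistics_oracle(self, rng):
        vals = rng.normal(8, 0.5, 22)
        res = self._results({f"G{i:02d}": v for i, v in enumerate(vals)})
        summary = summarize_ensemble(res)
        row = summary[(summary["decade"] == "2010s") & (summary["variable"] == "opd")].iloc[0]
        # manual type-7: linear interpolation between order statistics
        srt = np.sort(vals)
        for p in (10, 25, 75, 90):
            h = (len(srt) - 1) * p / 100.0
            lo, frac = int(np.floor(h)), h - int(np.floor(h))
            expect = srt[lo] + frac * (srt[lo + 1] - srt[lo]) if frac else srt[lo]
            assert row[f"p{p}"] == pytest.approx(expect, rel=1e-12)

    def test_percentile_ordering_invariant(self, rng):
        for _ in range(100):
            vals = rng.normal(8, rng.uniform(0.1, 2), 10)
            res = self._results({f"G{i}": v for i, v in enumerate(vals)})
            row = summarize_ensemble(res).iloc[0]
            assert row["p10"] <= row["p25"] <= row["median"] <= row["p75"] <= row["p90"]

    def test_percent_change_is_per_member_then_summarised(self):
        # two members with different baselines: mean of per-member changes
        # differs from the change of ensemble means — the former is reported
        res = pd.DataFrame(
            [
                dict(station_id="A", gcm_id="G1", decade="2010s", scenario="s", opd=5.0, yield_opd=5.0),
                dict(station_id="A", gcm_id="G1", decade="2030s", scenario="s", opd=10.0, yield_opd=10.0),
                dict(station_id="A", gcm_id="G2", decade="2010s", scenario="s", opd=10.0, yield_opd=10.0),
                dict(station_id="A", gcm_id="G2", decade="2030s", scenario="s", opd=10.0, yield_opd=10.0),
            ]
        )
        summary = summarize_ensemble(res)
        row = summary[(summary["decade"] == "2030s") & (summary["variable"] == "opd")].iloc[0]
        assert row["pct_change_mean"] == pytest.approx(50.0)  # (100% + 0%) / 2
        # ensemble-of-means change would be (10 − 7.5)/7.5 = 33.3%
        assert row["pct_change_mean"] != pytest.approx(100 * (10 / 7.5 - 1))

    def test_single_member_flagged(self, caplog):
        res = self._results({"G1": 8.0})
        summary = summarize_ensemble(res)
        assert summary["degenerate"].all()


class TestTrend:
    def test_exact_line(self):
        years = np.arange(2000, 2010)
        model, pred = extrapolate_trend(years, 0.05 * years - 94.0, 2035)
        assert pred == pytest.approx(0.05 * 2035 - 94.0, rel=1e-12)
        assert model.slope_per_decade == pytest.approx(0.5, rel=1e-12)

    def test_constant_series(self):
        years = np.arange(2000, 2010)
        _, pred = extrapolate_trend(years, np.full(10, 6.0), 2035)
        assert pred == pytest.approx(6.0, rel=1e-12)

    def test_matches_closed_form_ols(self, rng):
        years = np.arange(2000, 2020)
        values = 0.05 * years - 94 + rng.normal(0, 0.2, 20)
        model, pred = extrapolate_trend(years, values, 2035)
        x, y = years.astype(float), values
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        assert model.slope_per_year == pytest.approx(slope, abs=1e-10)
        assert pred == pytest.approx(intercept + slope * 2035, abs=1e-10)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            extrapolate_trend([2000, 2001, 2002, 2003], [1, 2, 3, 4], 2035)
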