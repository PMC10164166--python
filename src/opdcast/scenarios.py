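"""Station-level density/yield projection and scenario accounting.

Applies the trained density surrogate to station records under the
observed climate and under per-GCM future climates, optionally with soil
organic matter raised to a management threshold; computes density and
yield gaps against farmer practice; summarizes GCM ensembles by decade;
and extrapolates historical national trends.

Decade projections predict the optimum density for every season (year)
separately and then average within the decade; percent changes are
computed per GCM member against that member's own baseline decade before
the ensemble is summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agroclimate import GddParams, aggregate_seasons
from .opd_model import FEATURES, TrainedModel
from .trial_curves import LinearYieldModel

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "TrendModel",
    "DEFAULT_DECADES",
    "predict_station_optima",
    "compute_gaps",
    "apply_som_improvement",
    "project_decades",
    "project_decades_multi",
    "summarize_ensemble",
    "extrapolate_trend",
]

#: Current and future decades used throughout: the 2010s and the 2030s.
DEFAULT_DECADES = ((2010, 2019), (2030, 2039))


@dataclass(frozen=True)
class ScenarioSpec:
    """A named projection scenario.

    ``som_threshold`` (g kg⁻¹) triggers the soil-improvement variant in
    which station SOM is raised to the threshold wherever it is below;
    ``None`` keeps current soil. ``decades`` are inclusive year windows.
    """

    name: str
    som_threshold: Optional[float] = None
    climate: str = "gcm_ensemble"  # or "current"
    decades: tuple[tuple[int, int], ...] = DEFAULT_DECADES

    def __post_init__(self) -> None:
        for start, end in self.decades:
            if end - start != 9:
                raise ValueError(f"decade ({start}, {end}) is not a 10-year window")

    def decade_label(self, window: tuple[int, int]) -> str:
        return f"{window[0]}s"


def _check_station_features(stations: pd.DataFrame) -> None:
    missing = [c for c in ("station_id",) + FEATURES if c not in stations.columns]
    if missing:
        raise ValueError(f"stations table missing columns: {missing}")


def predict_station_optima(
    model: TrainedModel,
    yield_model: LinearYieldModel,
    stations: pd.DataFrame,
    scenario: str = "current",
) -> pd.DataFrame:
    """Predict OPD (surrogate) and Yield_OPD (linear relation) per station."""
    _check_station_features(stations)
    opd = model.predict(stations)
    out = pd.DataFrame(
        {
            "station_id": stations["station_id"].to_numpy(),
            "gcm_id": "observed",
            "decade": "2010s",
            "scenario": scenario,
            "opd": opd,
            "yield_opd": yield_model.predict(opd),
        }
    )
    if "region" in stations.columns:
        out.insert(1, "region", stations["region"].to_numpy())
    return out


def compute_gaps(results: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Gap table against farmer practice.

    density_gap = OPD − farmer density; yield_gap = Yield_OPD − farmer
    yield; attainment = farmer density / OPD; yield_improvement_pct =
    yield gap / farmer yield × 100 (NaN where farmer yield is zero).
    """
    need = {"station_id", "farmer_density", "farmer_yield"}
    if not need <= set(stations.columns):
        raise ValueError(f"stations table missing columns: {sorted(need - set(stations.columns))}")
    merged = results.merge(
        stations[["station_id", "farmer_density", "farmer_yield"]],
        on="station_id",
        how="inner",
        validate="many_to_one",
    )
    if len(merged) < len(results):
        logger.warning("%d result rows had no matching station", len(results) - len(merged))
    merged["density_gap"] = merged["opd"] - merged["farmer_density"]
    merged["yield_gap"] = merged["yield_opd"] - merged["farmer_yield"]
    merged["attainment"] = merged["farmer_density"] / merged["opd"]
    fy = merged["farmer_yield"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(fy > 0, merged["yield_gap"].to_numpy() / fy * 100.0, np.nan)
    if np.any(fy == 0):
        logger.warning("yield improvement undefined for %d station(s) with zero farmer yield",
                       int(np.sum(fy == 0)))
    merged["yield_improvement_pct"] = pct
    return merged


def apply_som_improvement(som, threshold: float = 20.0):
    """Raise SOM to the management threshold where it falls below.

    Returns max(som, threshold) — soils already above are never lowered.
    """
    if threshold < 0:
        raise ValueError("SOM threshold must be non-negative")
    som = np.asarray(som, dtype=float)
    if np.any(som < 0):
        raise ValueError("SOM must be non-negative")
    out = np.maximum(som, threshold)
    return float(out) if out.ndim == 0 else out


def project_decades_multi(
    model: TrainedModel,
    yield_model: LinearYieldModel,
    stations: pd.DataFrame,
    gcm_series: Iterable[tuple[str, pd.DataFrame]],
    specs: Sequence[ScenarioSpec],
    gdd_params: GddParams = GddParams(),
    average_climate_first: bool = False,
) -> pd.DataFrame:
    """Per station × GCM × decade optimum density under several scenarios.

    ``gcm_series`` yields (gcm_id, daily frame) pairs; each daily frame
    holds season-window weather with columns station_id, year, tmax,
    tmin, prec, radn and must cover every year of every decade of every
    spec. Season predictors are computed once per member and year, the
    density surrogate is applied per year, and predictions are averaged
    within each decade (``average_climate_first`` instead averages the
    predictors over the decade and predicts once).
    """
    if "som" not in stations.columns:
        raise ValueError("stations table needs a som column")
    base_som = stations.set_index("station_id")["som"]
    som_by_spec = {}
    for spec in specs:
        if spec.som_threshold is not None:
            som_by_spec[spec.name] = pd.Series(
                apply_som_improvement(base_som.to_numpy(), spec.som_threshold),
                index=base_som.index,
            )
        else:
            som_by_spec[spec.name] = base_som
    regions = (
        stations.set_index("station_id")["region"] if "region" in stations.columns else None
    )
    n_stations = stations["station_id"].nunique()

    chunks = []
    n_members = 0
    for gcm_id, daily in gcm_series:
        n_members += 1
        feats = aggregate_seasons(daily, gdd_params)
        for spec in specs:
            for window in spec.decades:
                label = spec.decade_label(window)
                dec = feats[(feats["year"] >= window[0]) & (feats["year"] <= window[1])]
                got = dec.groupby("station_id")["year"].nunique()
                n_years = window[1] - window[0] + 1
                if len(got[got < n_years]) or len(got) < n_stations:
                    raise ValueError(
                        f"GCM {gcm_id} is missing years in decade {label}"
                    )
                som = som_by_spec[spec.name]
                dec = dec.assign(som=dec["station_id"].map(som).to_numpy())
                if average_climate_first:
                    dec = dec.groupby("station_id", as_index=False)[list(FEATURES)].mean()
                    per_station = pd.DataFrame(
                        {"station_id": dec["station_id"], "opd": model.predict(dec)}
                    )
                else:
                    dec = dec.assign(opd_pred=model.predict(dec))
                    per_station = (
                        dec.groupby("station_id", as_index=False)["opd_pred"]
                        .mean()
                        .rename(columns={"opd_pred": "opd"})
                    )
                per_station["yield_opd"] = yield_model.predict(per_station["opd"])
                per_station["gcm_id"] = gcm_id
                per_station["decade"] = label
                per_station["scenario"] = spec.name
                if regions is not None:
                    per_station["region"] = per_station["station_id"].map(regions)
                chunks.append(per_station)
    if n_members == 0:
        raise ValueError("gcm_series produced no members")
    return pd.concat(chunks, ignore_index=True)


def project_decades(
    model: TrainedModel,
    yield_model: LinearYieldModel,
    stations: pd.DataFrame,
    gcm_series: Iterable[tuple[str, pd.DataFrame]],
    spec: ScenarioSpec,
    gdd_params: GddParams = GddParams(),
    average_climate_first: bool = False,
) -> pd.DataFrame:
    """Single-scenario convenience wrapper around
    :func:`project_decades_multi`."""
    return project_decades_multi(
        model, yield_model, stations, gcm_series, [spec], gdd_params,
        average_climate_first,
    )


_PCTS = (10, 25, 75, 90)


def _member_region_means(results: pd.DataFrame) -> pd.DataFrame:
    """Region-mean (plus national 'ALL') opd/yield per member × decade."""
    base = results.copy()
    if "region" not in base.columns:
        base["region"] = "ALL"
        frames = [base]
    else:
        nat = base.copy()
        nat["region"] = "ALL"
        frames = [base, nat]
    stacked = pd.concat(frames, ignore_index=True)
    return (
        stacked.groupby(["scenario", "gcm_id", "decade", "region"], as_index=False)[
            ["opd", "yield_opd"]
        ].mean()
    )


def summarize_ensemble(
    results: pd.DataFrame, baseline_decade: str = "2010s"
) -> pd.DataFrame:
    """Distribution of region-mean projections across GCM members.

    Returns one row per scenario × decade × region × variable with the
    ensemble mean, median and 10/25/75/90th percentiles (linear
    interpolation between order statistics), plus the same summaries of
    per-member percent change relative to ``baseline_decade``. With a
    single member the percentiles are degenerate and flagged.
    """
    means = _member_region_means(results)
    n_members = means["gcm_id"].nunique()
    if n_members < 2:
        logger.warning("single ensemble member: percentiles are degenerate")
    long = means.melt(
        id_vars=["scenario", "gcm_id", "decade", "region"],
        value_vars=["opd", "yield_opd"],
        var_name="variable",
    )
    base = long[long["decade"] == baseline_decade].rename(columns={"value": "base"})
    long = long.merge(
        base[["scenario", "gcm_id", "region", "variable", "base"]],
        on=["scenario", "gcm_id", "region", "variable"],
        how="left",
    )
    long["pct_change"] = (long["value"] / long["base"] - 1.0) * 100.0

    def _summary(g: pd.DataFrame) -> pd.Series:
        v = g["value"].to_numpy()
        out = {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "n_members": int(len(v)),
            "degenerate": len(v) < 2,
        }
        for p in _PCTS:
            out[f"p{p}"] = float(np.percentile(v, p))  # type-7 linear interpolation
        c = g["pct_change"].to_numpy()
        out["pct_change_mean"] = float(np.mean(c))
        out["pct_change_median"] = float(np.median(c))
        return pd.Series(out)

    summary = (
        long.groupby(["scenario", "decade", "region", "variable"])
        .apply(_summary, include_groups=False)
        .reset_index()
    )
    return summary


@dataclass(frozen=True)
class TrendModel:
    """Linear trend of a national annual series."""

    slope_per_year: float
    intercept: float
    window: tuple[int, int]
    r2: float

    @property
    def slope_per_decade(self) -> float:
        return self.slope_per_year * 10.0

    def predict(self, year):
        return self.intercept + self.slope_per_year * np.asarray(year, dtype=float)


def extrapolate_trend(
    years: Sequence[int], values: Sequence[float], target_year: int
) -> tuple[TrendModel, float]:
    """OLS trend through annual national values, evaluated at a future year."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 5:
        raise ValueError(f"need ≥5 annual points, got {years.size}")
    res = stats.linregress(years, values)
    model = TrendModel(
        slope_per_year=float(res.slope),
        intercept=float(res.intercept),
        window=(int(years.min()), int(years.max())),
        r2=float(res.rvalue**2),
    )
    return model, float(model.predict(target_year))
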