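"""CSV schemas, validation, and the pipeline configuration.

Column names carry their units (density_1e4_ha, som_g_kg, prec_mm) to
prevent silent scale errors. Validation collects every violation before
raising, reporting row numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .trial_curves import REGIONS, DensityTrial, OPDRecord
from .agroclimate import SeasonPredictors

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "PipelineConfig",
    "load_config",
    "read_trials",
    "write_trials",
    "read_daily_weather",
    "write_daily_weather",
    "read_stations",
    "write_stations",
    "records_to_frame",
    "frame_to_records",
]

TRIAL_COLUMNS = (
    "trial_id", "site_id", "region", "year", "hybrid",
    "density_1e4_ha", "yield_mg_ha", "som_g_kg",
    "sowing_date", "maturity_date", "water_regime",
)
WEATHER_COLUMNS = ("station_id", "date", "tmax_c", "tmin_c", "prec_mm", "radn_mj_m2")
STATION_COLUMNS = (
    "station_id", "lat", "lon", "region", "som_g_kg",
    "sowing_date", "maturity_date", "farmer_density_1e4_ha", "farmer_yield_mg_ha",
)


class ValidationError(ValueError):
    """All schema violations of one table, collected before raising."""

    def __init__(self, table: str, problems: list[str]):
        self.table = table
        self.problems = problems
        listing = "\n  ".join(problems[:50])
        more = "" if len(problems) <= 50 else f"\n  (+{len(problems) - 50} more)"
        super().__init__(f"{len(problems)} problem(s) in {table}:\n  {listing}{more}")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML, echoed into outputs."""

    # synthetic generation (None → tables must be provided on disk)
    synth: Optional[dict] = field(default_factory=dict)
    # screening & curve fitting
    min_levels: int = 4
    # GDD bounds and Angstrom coefficients
    gdd_t_low: float = 10.0
    gdd_t_high: float = 30.0
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50
    # surrogate hyperparameters
    n_trees: int = 500
    m_try: int = 3
    seed: int = 42
    run_loo: bool = False
    # scenario settings
    som_threshold: float = 20.0
    decades: tuple = ((2010, 2019), (2030, 2039))
    trend_target_year: int = 2035
    # demand accounting (Mt / persons); baseline calibrated to reported
    # national totals (≈290.8 Mt apparent demand at 1.428e9 people)
    demand: dict = field(
        default_factory=lambda: dict(
            production=272.0, imports=23.0, exports=0.0, stock_change=4.2,
            population_base=1.428e9, population_target=1.434e9, target_year=2035,
        )
    )
    # harvested area by region (ha), ~42 Mha nationally
    area_ha: dict = field(
        default_factory=lambda: dict(NE=14.0e6, NCP=13.5e6, NW=6.5e6, SW=8.0e6)
    )
    outdir: str = "opdcast_out"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(str(path), [f"unknown config key: {k}" for k in sorted(unknown)])
    if "decades" in raw:
        raw["decades"] = tuple(tuple(d) for d in raw["decades"])
    return PipelineConfig(**raw)


def _parse_dates(frame: pd.DataFrame, col: str, problems: list[str]) -> pd.Series:
    parsed = pd.to_datetime(frame[col], format="%Y-%m-%d", errors="coerce")
    for i in frame.index[parsed.isna() & frame[col].notna()]:
        problems.append(f"row {i}: unparseable ISO-8601 date in {col}: {frame[col][i]!r}")
    return parsed.dt.date


def _check_columns(frame: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValidationError(table, [f"missing column: {c}" for c in missing])


def read_trials(path: str | Path) -> list[DensityTrial]:
    """Read long-format trial CSV (one row per density level) into trials.

    All violations (bad region, negative density, unparseable dates, ...)
    are collected and raised together with their row numbers.
    """
    frame = pd.read_csv(path)
    _check_columns(frame, TRIAL_COLUMNS, str(path))
    problems: list[str] = []
    bad_region = ~frame["region"].isin(REGIONS)
    for i in frame.index[bad_region]:
        problems.append(f"row {i}: region {frame['region'][i]!r} not in {REGIONS}")
    for i in frame.index[frame["density_1e4_ha"] <= 0]:
        problems.append(f"row {i}: non-positive density {frame['density_1e4_ha'][i]}")
    for i in frame.index[frame["yield_mg_ha"] < 0]:
        problems.append(f"row {i}: negative yield {frame['yield_mg_ha'][i]}")
    sowing = _parse_dates(frame, "sowing_date", problems)
    maturity = _parse_dates(frame, "maturity_date", problems)
    if problems:
        raise ValidationError(str(path), problems)
    frame = frame.assign(_sowing=sowing, _maturity=maturity)

    trials = []
    for trial_id, grp in frame.groupby("trial_id", sort=False):
        first = grp.iloc[0]
        trials.append(
            DensityTrial(
                trial_id=str(trial_id),
                site_id=str(first["site_id"]),
                region=str(first["region"]),
                year=int(first["year"]),
                hybrid=str(first["hybrid"]),
                densities=grp["density_1e4_ha"].to_numpy(float),
                yields=grp["yield_mg_ha"].to_numpy(float),
                som=float(first["som_g_kg"]),
                sowing=first["_sowing"],
                maturity=first["_maturity"],
                water_regime=str(first["water_regime"]),
            )
        )
    return trials


def write_trials(trials: Sequence[DensityTrial], path: str | Path) -> None:
    rows = []
    for t in trials:
        for d, y in zip(t.densities, t.yields):
            rows.append(
                dict(
                    trial_id=t.trial_id, site_id=t.site_id, region=t.region,
                    year=t.year, hybrid=t.hybrid, density_1e4_ha=d, yield_mg_ha=y,
                    som_g_kg=t.som, sowing_date=t.sowing.isoformat(),
                    maturity_date=t.maturity.isoformat(), water_regime=t.water_regime,
                )
            )
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(path, index=False)


def read_daily_weather(path: str | Path) -> pd.DataFrame:
    """Daily weather CSV → internal frame (station_id, year, date, tmax, ...)."""
    frame = pd.read_csv(path)
    _check_columns(frame, WEATHER_COLUMNS, str(path))
    problems: list[str] = []
    dates = pd.to_datetime(frame["date"], errors="coerce")
    for i in frame.index[dates.isna()]:
        problems.append(f"row {i}: unparseable date {frame['date'][i]!r}")
    bad = frame["tmax_c"] < frame["tmin_c"]
    for i in frame.index[bad][:20]:
        problems.append(f"row {i}: tmax < tmin")
    for i in frame.index[frame["prec_mm"] < 0][:20]:
        problems.append(f"row {i}: negative precipitation")
    if problems:
        raise ValidationError(str(path), problems)
    return pd.DataFrame(
        dict(
            station_id=frame["station_id"], year=dates.dt.year, date=dates,
            tmax=frame["tmax_c"], tmin=frame["tmin_c"],
            prec=frame["prec_mm"], radn=frame["radn_mj_m2"],
        )
    )


def write_daily_weather(daily: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        dict(
            station_id=daily["station_id"],
            date=pd.to_datetime(daily["date"]).dt.strftime("%Y-%m-%d"),
            tmax_c=daily["tmax"], tmin_c=daily["tmin"],
            prec_mm=daily["prec"], radn_mj_m2=daily["radn"],
        )
    )
    out.to_csv(path, index=False, float_format="%.4f")


def read_stations(path: str | Path) -> pd.DataFrame:
    """Station metadata CSV → internal frame (som column in g kg⁻¹).

    Accepts soc_pct instead of som_g_kg, converting ×1.724 (the SOM
    column wins when both are present).
    """
    from .agroclimate import soc_to_som

    frame = pd.read_csv(path)
    cols = [c for c in STATION_COLUMNS if c != "som_g_kg"]
    _check_columns(frame, cols, str(path))
    problems: list[str] = []
    if "som_g_kg" not in frame.columns:
        if "soc_pct" not in frame.columns:
            problems.append("missing column: som_g_kg (or soc_pct)")
        else:
            frame["som_g_kg"] = soc_to_som(frame["soc_pct"].to_numpy()) * 10.0  # % → g/kg
    for i in frame.index[~frame["region"].isin(REGIONS)]:
        problems.append(f"row {i}: region {frame['region'][i]!r} not in {REGIONS}")
    for i in frame.index[frame["farmer_density_1e4_ha"] <= 0]:
        problems.append(f"row {i}: non-positive farmer density")
    sowing = _parse_dates(frame, "sowing_date", problems)
    maturity = _parse_dates(frame, "maturity_date", problems)
    if problems:
        raise ValidationError(str(path), problems)
    return pd.DataFrame(
        dict(
            station_id=frame["station_id"], region=frame["region"],
            lat=frame["lat"], lon=frame["lon"], som=frame["som_g_kg"],
            sowing=sowing, maturity=maturity,
            farmer_density=frame["farmer_density_1e4_ha"],
            farmer_yield=frame["farmer_yield_mg_ha"],
        )
    )


def write_stations(stations: pd.DataFrame, path: str | Path) -> None:
    def _dates(col, fallback_doy):
        if col in stations.columns:
            return stations[col].astype(str)
        doy = stations[fallback_doy]
        base = pd.to_datetime("2015-01-01")
        return (base + pd.to_timedelta(doy - 1, unit="D")).dt.strftime("%Y-%m-%d")

    sow = _dates("sowing", "sow_doy")
    if "maturity" in stations.columns:
        mat = stations["maturity"].astype(str)
    else:
        base = pd.to_datetime("2015-01-01")
        mat = (
            base
            + pd.to_timedelta(stations["sow_doy"] + stations["season_len"] - 2, unit="D")
        ).dt.strftime("%Y-%m-%d")
    out = pd.DataFrame(
        dict(
            station_id=stations["station_id"], lat=stations["lat"], lon=stations["lon"],
            region=stations["region"], som_g_kg=stations["som"],
            sowing_date=sow, maturity_date=mat,
            farmer_density_1e4_ha=stations["farmer_density"],
            farmer_yield_mg_ha=stations["farmer_yield"],
        )
    )
    out.to_csv(path, index=False, float_format="%.6f")


def records_to_frame(records: Sequence[OPDRecord]) -> pd.DataFrame:
    """OPD records (with fit diagnostics and predictors) as a tidy frame."""
    rows = []
    for r in records:
        row = dict(
            trial_id=r.trial_id, region=r.region, opd=r.opd, yield_opd=r.yield_opd,
            valid=r.valid, reason=r.reason,
        )
        if r.fit is not None:
            row.update(fit_a=r.fit.a, fit_b=r.fit.b, fit_c=r.fit.c,
                       fit_r2=r.fit.r2, n_points=r.fit.n_points)
        if r.predictors is not None:
            p = r.predictors
            row.update(tmin_mean=p.tmin_mean, tmax_mean=p.tmax_mean,
                       prec_sum=p.prec_sum, radn_sum=p.radn_sum,
                       gdd_sum=p.gdd_sum, som=p.som)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[OPDRecord]:
    records = []
    for _, row in frame.iterrows():
        predictors = None
        if "tmin_mean" in frame.columns and not pd.isna(row["tmin_mean"]):
            predictors = SeasonPredictors(
                tmin_mean=row["tmin_mean"], tmax_mean=row["tmax_mean"],
                prec_sum=row["prec_sum"], radn_sum=row["radn_sum"],
                gdd_sum=row["gdd_sum"], som=row["som"],
            )
        records.append(
            OPDRecord(
                trial_id=str(row["trial_id"]), opd=row["opd"], yield_opd=row["yield_opd"],
                valid=bool(row["valid"]), reason=str(row.get("reason", "") or ""),
                predictors=predictors, region=str(row.get("region", "") or ""),
            )
        )
    return records
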