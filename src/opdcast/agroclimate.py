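"""Growing-season agro-climate features.

Computes the predictor set used by the density surrogate: growing degree
days with both temperature bounds clamped, seasonal means/sums of daily
weather, Angstrom–Prescott conversion of sunshine hours to global solar
radiation, and the SOC→SOM conversion.

Units follow the column conventions used throughout the package:
temperatures in °C, precipitation in mm, radiation in MJ m⁻², soil organic
matter (SOM) in g kg⁻¹, soil organic carbon (SOC) in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GddParams",
    "SeasonPredictors",
    "GapError",
    "daily_gdd",
    "season_predictors",
    "aggregate_seasons",
    "extraterrestrial_radiation",
    "daylength_hours",
    "sunshine_to_radiation",
    "soc_to_som",
    "SOC_TO_SOM_FACTOR",
]

#: Van Bemmelen factor: SOM = SOC × 1.724.
SOC_TO_SOM_FACTOR = 1.724

#: Solar constant in MJ m⁻² min⁻¹ (FAO-56).
_GSC = 0.0820


@dataclass(frozen=True)
class GddParams:
    """Temperature bounds for growing-degree-day accumulation (°C).

    Both the daily maximum and the daily minimum are clamped into
    [t_low, t_high] before averaging; the base subtracted is t_low.
    """

    t_low: float = 10.0
    t_high: float = 30.0

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError(f"t_low must be < t_high, got {self.t_low} >= {self.t_high}")


@dataclass(frozen=True)
class SeasonPredictors:
    """Six-feature growing-season summary driving the density surrogate."""

    tmin_mean: float  # °C
    tmax_mean: float  # °C
    prec_sum: float   # mm
    radn_sum: float   # MJ m⁻²
    gdd_sum: float    # °C·d
    som: float        # g kg⁻¹

    def __post_init__(self) -> None:
        if self.gdd_sum < 0 or self.prec_sum < 0 or self.radn_sum < 0:
            raise ValueError("season sums must be non-negative")


class GapError(ValueError):
    """Raised when a weather series does not cover the season window."""

    def __init__(self, missing: list[date]):
        self.missing = missing
        preview = ", ".join(str(d) for d in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        super().__init__(f"missing weather for {len(missing)} day(s): {preview}{more}")


def daily_gdd(tmax, tmin, params: GddParams = GddParams()):
    """Daily growing degree days with double clamping.

    Both temperatures are independently clamped to [t_low, t_high]; the
    daily heat unit is the mean of the clamped values minus t_low, hence
    bounded in [0, t_high − t_low]. Accepts scalars or arrays.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in daily weather input")
    tmax_c = np.clip(tmax, params.t_low, params.t_high)
    tmin_c = np.clip(tmin, params.t_low, params.t_high)
    out = (tmax_c + tmin_c) / 2.0 - params.t_low
    return float(out) if out.ndim == 0 else out


def _required_columns(frame: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"weather frame missing columns: {missing}")


def season_predictors(
    series: pd.DataFrame,
    season: tuple[date, date],
    som: float,
    params: GddParams = GddParams(),
    interpolate_gaps: bool = False,
    max_gap_days: int = 3,
) -> SeasonPredictors:
    """Aggregate a daily weather series over one growing season.

    ``series`` needs columns date, tmax, tmin, prec, radn. The window
    [sowing, maturity] is inclusive at both ends. Missing days raise
    :class:`GapError` unless ``interpolate_gaps`` is set and every gap is
    at most ``max_gap_days`` long, in which case values are linearly
    interpolated.
    """
    sowing, maturity = season
    if sowing > maturity:  # a one-day season is allowed
        raise ValueError(f"sowing {sowing} must not be after maturity {maturity}")
    _required_columns(series, ("date", "tmax", "tmin", "prec", "radn"))

    df = series.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df = df[(df["date"] >= sowing) & (df["date"] <= maturity)].sort_values("date")
    n_days = (maturity - sowing).days + 1
    expected = {sowing + timedelta(days=i) for i in range(n_days)}
    missing = sorted(expected - set(df["date"]))
    if missing:
        if not interpolate_gaps:
            raise GapError(missing)
        idx = pd.date_range(sowing, maturity, freq="D")
        df = (
            df.set_index(pd.to_datetime(df["date"]))
            .reindex(idx)
            .drop(columns=["date"])
        )
        run_lengths = (
            df["tmax"].isna().astype(int).groupby(df["tmax"].notna().cumsum()).sum()
        )
        if run_lengths.max() > max_gap_days:
            raise GapError(missing)
        df = df.interpolate(method="linear", limit_direction="both")
        logger.info("interpolated %d missing day(s) in season window", len(missing))

    gdd = daily_gdd(df["tmax"].to_numpy(), df["tmin"].to_numpy(), params)
    return SeasonPredictors(
        tmin_mean=float(df["tmin"].mean()),
        tmax_mean=float(df["tmax"].mean()),
        prec_sum=float(df["prec"].sum()),
        radn_sum=float(df["radn"].sum()),
        gdd_sum=float(np.sum(gdd)),
        som=float(som),
    )


def aggregate_seasons(
    daily: pd.DataFrame,
    params: GddParams = GddParams(),
    group_cols: tuple[str, ...] = ("station_id", "year"),
) -> pd.DataFrame:
    """Vectorised per-season aggregation for bulk projection runs.

    ``daily`` must already be restricted to season-window days and carry
    the grouping columns plus tmax, tmin, prec, radn. Returns one row per
    group with tmin_mean, tmax_mean, prec_sum, radn_sum, gdd_sum.
    """
    _required_columns(daily, group_cols + ("tmax", "tmin", "prec", "radn"))
    daily = daily.assign(
        _gdd=daily_gdd(daily["tmax"].to_numpy(), daily["tmin"].to_numpy(), params)
    )
    agg = daily.groupby(list(group_cols), sort=False).agg(
        tmin_mean=("tmin", "mean"),
        tmax_mean=("tmax", "mean"),
        prec_sum=("prec", "sum"),
        radn_sum=("radn", "sum"),
        gdd_sum=("_gdd", "sum"),
    )
    return agg.reset_index()


def extraterrestrial_radiation(latitude: float, day_of_year: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m⁻² d⁻¹), FAO-56 eq. 21."""
    _check_solar_inputs(latitude, day_of_year)
    phi = np.radians(latitude)
    dr = 1 + 0.033 * np.cos(2 * np.pi / 365 * day_of_year)
    delta = 0.409 * np.sin(2 * np.pi / 365 * day_of_year - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (
        24 * 60 / np.pi
        * _GSC
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return float(ra)


def daylength_hours(latitude: float, day_of_year: int) -> float:
    """Maximum possible sunshine duration N (h), FAO-56 eq. 34."""
    _check_solar_inputs(latitude, day_of_year)
    phi = np.radians(latitude)
    delta = 0.409 * np.sin(2 * np.pi / 365 * day_of_year - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return float(24 / np.pi * ws)


def _check_solar_inputs(latitude: float, day_of_year: int) -> None:
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day_of_year out of range: {day_of_year}")
    if abs(latitude) >= 66.5:
        raise ValueError("latitude beyond polar circle not supported")


def sunshine_to_radiation(
    sunshine_hours: float,
    latitude: float,
    day_of_year: int,
    a: float = 0.25,
    b: float = 0.50,
) -> float:
    """Global solar radiation from sunshine duration (Angstrom–Prescott).

    Rs = (a + b·n/N)·Ra with Ra and N from FAO-56; n is capped at the
    astronomical daylength N. Defaults a=0.25, b=0.50 are the FAO-56
    recommendations where no local calibration exists.
    """
    if sunshine_hours < 0:
        raise ValueError("sunshine hours must be non-negative")
    n_max = daylength_hours(latitude, day_of_year)
    n = min(float(sunshine_hours), n_max)
    ra = extraterrestrial_radiation(latitude, day_of_year)
    return (a + b * n / n_max) * ra


def soc_to_som(soc):
    """Convert soil organic carbon to soil organic matter (×1.724).

    Unit-preserving: percent in → percent out, g kg⁻¹ in → g kg⁻¹ out.
    """
    soc = np.asarray(soc, dtype=float)
    if np.any(soc < 0):
        raise ValueError("SOC must be non-negative")
    out = soc * SOC_TO_SOM_FACTOR
    return float(out) if out.ndim == 0 else out
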