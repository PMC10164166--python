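"""Synthetic trials, stations and pseudo-GCM ensembles with a known truth.

Every pipeline stage can be exercised without external downloads: the
generator emits multi-density trials, station records with daily weather,
and a 22-member future-climate ensemble, all driven by a known additive
ground-truth density surface so that parameter recovery is checkable.

The truth surface is additive in the six predictors with a single hinge
nonlinearity in SOM (response flat above a knot, default 20 g kg⁻¹) and is
calibrated to the study conditions it emulates: a national mean optimum
density near 7.8 ×10⁴ plants ha⁻¹ with regional means between ~7 and ~8.8,
optimum density decreasing with growing-season mean Tmin (−0.18 per °C),
increasing with seasonal radiation (+1.6 per 1000 MJ m⁻²), farmer densities
15–30% below the optimum, and farmer yields about half the attainable
yield. Pseudo-GCM members share one stochastic weather realization across
decades so that decade contrasts isolate the imposed warming trend.

All generators are bit-reproducible under a fixed seed (independent child
streams derived from one ``numpy.random.SeedSequence``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .agroclimate import daily_gdd
from .trial_curves import REGIONS, DensityTrial

logger = logging.getLogger(__name__)

__all__ = [
    "TruthSurface",
    "SynthConfig",
    "SyntheticStations",
    "generate_stations",
    "generate_trials",
    "generate_future_climate",
    "generate_national_history",
    "generate_field_trials",
    "write_truth",
]

# Region growing-season climatology: daily tmin/tmax (°C), daily mean
# radiation (MJ m⁻²), daily mean precipitation (mm), wet-day probability,
# nominal sowing day-of-year. NE is coolest, SW the wettest.
_CLIMATOLOGY = {
    "NE": dict(tmin=15.0, tmax=26.0, radn=18.0, prec=3.2, p_wet=0.35, sow_doy=120),
    "NCP": dict(tmin=18.0, tmax=29.0, radn=17.0, prec=3.6, p_wet=0.35, sow_doy=130),
    "NW": dict(tmin=15.5, tmax=28.0, radn=21.0, prec=1.6, p_wet=0.20, sow_doy=125),
    "SW": dict(tmin=17.0, tmax=26.0, radn=14.0, prec=5.6, p_wet=0.50, sow_doy=110),
}

_LAT_LON = {
    "NE": ((42.0, 48.0), (122.0, 132.0)),
    "NCP": ((34.0, 40.0), (113.0, 120.0)),
    "NW": ((35.0, 43.0), (95.0, 110.0)),
    "SW": ((23.0, 30.0), (100.0, 108.0)),
}


@dataclass(frozen=True)
class TruthSurface:
    """Generative optimum-density function over the six predictors.

    opd = intercept + Σ coef·x, with the SOM term using min(som, knot);
    the result is clipped to ``opd_range``. Yield at the optimum follows
    yield_opd = yield_alpha + yield_beta·opd.
    """

    intercept: float = 4.05
    coef: dict = field(
        default_factory=lambda: dict(
            tmin_mean=-0.18, tmax_mean=-0.02, prec_sum=0.0004,
            radn_sum=0.0016, gdd_sum=0.0001, som=0.16,
        )
    )
    som_knot: float = 20.0      # g kg⁻¹, response flat above this
    opd_range: tuple = (4.0, 12.0)
    yield_alpha: float = 2.1    # Mg ha⁻¹
    yield_beta: float = 1.2     # Mg ha⁻¹ per 10⁴ plants ha⁻¹

    def opd(self, predictors: pd.DataFrame) -> np.ndarray:
        x = self.intercept + sum(
            self.coef[k]
            * (
                np.minimum(predictors[k].to_numpy(dtype=float), self.som_knot)
                if k == "som"
                else predictors[k].to_numpy(dtype=float)
            )
            for k in self.coef
        )
        return np.clip(x, *self.opd_range)

    def yield_at_opd(self, opd) -> np.ndarray:
        return self.yield_alpha + self.yield_beta * np.asarray(opd, dtype=float)

    def effect_sizes(self, predictors: pd.DataFrame) -> dict:
        """|coef| × predictor spread: the true importance ranking."""
        out = {}
        for k, c in self.coef.items():
            x = predictors[k].to_numpy(dtype=float)
            if k == "som":
                x = np.minimum(x, self.som_knot)
            out[k] = abs(c) * float(np.std(x))
        return out


@dataclass(frozen=True)
class SynthConfig:
    """Sizes, noise levels and climate-trend settings of the generator."""

    n_trials: int = 448
    n_stations: int = 402
    n_gcms: int = 22
    seed: int = 42
    region_props: dict = field(
        default_factory=lambda: {"NE": 0.30, "NCP": 0.35, "NW": 0.15, "SW": 0.20}
    )
    warming_delta_mean: float = 0.8  # °C, ensemble-mean Tmin/Tmax rise 2010s→2030s
    warming_delta_sd: float = 0.3    # °C, spread across members
    prec_scale_sd: float = 0.05      # fractional precipitation change spread
    temp_noise_sd: float = 1.8       # °C, daily AR(1) innovations
    ar1_rho: float = 0.7
    yield_noise_sd: float = 0.3      # Mg ha⁻¹, on trial yields
    hybrid_opd_sd: float = 0.15      # 10⁴ plants ha⁻¹, trial-level deviation
    som_median: float = 18.0         # g kg⁻¹ (lognormal, clipped to [5, 40])
    som_sigma: float = 0.30
    season_len_mean: float = 150.0   # days
    baseline_years: tuple = (2010, 2019)

    def __post_init__(self) -> None:
        if min(self.n_trials, self.n_stations, self.n_gcms) <= 0:
            raise ValueError("counts must be positive")
        if abs(sum(self.region_props.values()) - 1.0) > 1e-9:
            raise ValueError("region proportions must sum to 1")


@dataclass
class SyntheticStations:
    """Stations, their observed daily weather, and the hidden truth."""

    stations: pd.DataFrame   # public schema: station_id, region, lat, lon, som, ...
    daily: pd.DataFrame      # station_id, year, date, tmax, tmin, prec, radn
    truth: pd.DataFrame      # station_id, opd_true, yield_opd_true (tests only)
    config: SynthConfig
    surface: TruthSurface


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent child stream keyed by (seed, *key)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _season_days(year: int, sow_doy: int, season_len: int) -> np.ndarray:
    start = np.datetime64(date(year, 1, 1) + timedelta(days=int(sow_doy) - 1))
    return start + np.arange(season_len).astype("timedelta64[D]")


def _ar1_block(rng: np.random.Generator, shape: tuple, sd: float, rho: float) -> np.ndarray:
    """AR(1) noise along the last axis, stationary start, row-independent."""
    if sd == 0:
        return np.zeros(shape)
    innov = rng.normal(0.0, sd, shape)
    innov[..., 0] /= np.sqrt(1.0 - rho**2)
    return lfilter([1.0], [1.0, -rho], innov, axis=-1)


def _weather_block(
    rng: np.random.Generator,
    clim: dict,
    offsets: dict,
    n_years: int,
    n_days: int,
    temp_noise_sd: float,
    ar1_rho: float,
) -> dict:
    """Daily weather arrays of shape (n_years, n_days) for one station."""
    shape = np.sin(np.pi * np.arange(n_days) / max(n_days - 1, 1))
    shape = 3.0 * (shape - shape.mean())  # centred seasonal course, ±~2 °C
    dims = (n_years, n_days)
    tmin = clim["tmin"] + offsets["tmin"] + shape + _ar1_block(rng, dims, temp_noise_sd, ar1_rho)
    tmax = clim["tmax"] + offsets["tmax"] + shape + _ar1_block(rng, dims, temp_noise_sd, ar1_rho)
    tmax = np.maximum(tmax, tmin + 0.5)
    radn = np.clip(
        clim["radn"] + offsets["radn"] + rng.normal(0.0, 3.0, dims), 0.5, None
    )
    wet = rng.random(dims) < clim["p_wet"]
    prec = np.where(wet, rng.exponential(clim["prec"] / clim["p_wet"], dims), 0.0)
    prec = prec * offsets["prec_factor"]
    return dict(tmax=tmax, tmin=tmin, prec=prec, radn=radn)


def _station_frame(config: SynthConfig) -> pd.DataFrame:
    """Station metadata including the hidden per-station climate offsets."""
    rng = _rng(config.seed, 1)
    counts = {r: int(round(config.n_stations * p)) for r, p in config.region_props.items()}
    fix = config.n_stations - sum(counts.values())  # round-off to largest region
    counts[max(counts, key=counts.get)] += fix
    rows = []
    i = 0
    for region in REGIONS:
        (lat_lo, lat_hi), (lon_lo, lon_hi) = _LAT_LON[region]
        for _ in range(counts.get(region, 0)):
            i += 1
            rows.append(
                dict(
                    station_id=f"S{i:04d}",
                    region=region,
                    lat=rng.uniform(lat_lo, lat_hi),
                    lon=rng.uniform(lon_lo, lon_hi),
                    som=float(
                        np.clip(
                            rng.lognormal(np.log(config.som_median), config.som_sigma),
                            5.0, 40.0,
                        )
                    ),
                    sow_doy=int(_CLIMATOLOGY[region]["sow_doy"] + rng.integers(-7, 8)),
                    season_len=int(round(rng.normal(config.season_len_mean, 5.0))),
                    tmin_off=rng.normal(0.0, 1.0),
                    tmax_off=rng.normal(0.0, 1.0),
                    radn_off=rng.normal(0.0, 1.5),
                    # lognormal with mean 1 so the climatology is unbiased
                    prec_factor=float(rng.lognormal(-0.5 * 0.25**2, 0.25)),
                )
            )
    return pd.DataFrame(rows)


def _offsets(row) -> dict:
    return dict(
        tmin=row["tmin_off"], tmax=row["tmax_off"],
        radn=row["radn_off"], prec_factor=row["prec_factor"],
    )


def _assemble_daily(
    station_ids: list, years_list: list, dates_list: list, blocks: list
) -> pd.DataFrame:
    """Stack per-station (years × days) weather blocks into one tidy frame."""
    parts = {k: [] for k in ("tmax", "tmin", "prec", "radn")}
    sid_col, year_col, date_col = [], [], []
    for sid, years, dates, block in zip(station_ids, years_list, dates_list, blocks):
        n_years, n_days = block["tmax"].shape
        sid_col.append(np.repeat(sid, n_years * n_days))
        year_col.append(np.repeat(years, n_days))
        date_col.append(np.concatenate(dates))
        for k in parts:
            parts[k].append(block[k].ravel())
    return pd.DataFrame(
        dict(
            station_id=np.concatenate(sid_col),
            year=np.concatenate(year_col),
            date=np.concatenate(date_col),
            tmax=np.concatenate(parts["tmax"]),
            tmin=np.concatenate(parts["tmin"]),
            prec=np.concatenate(parts["prec"]),
            radn=np.concatenate(parts["radn"]),
        )
    )


def _station_daily(
    full: pd.DataFrame, years: range, config: SynthConfig, stream: int
) -> pd.DataFrame:
    """Season-window daily weather for every station × year."""
    yrs = np.array(list(years))
    sids, years_list, dates_list, blocks = [], [], [], []
    for idx, row in full.iterrows():
        clim = _CLIMATOLOGY[row["region"]]
        rng = _rng(config.seed, stream, idx)
        n_days = int(row["season_len"])
        blocks.append(
            _weather_block(rng, clim, _offsets(row), len(yrs), n_days,
                           config.temp_noise_sd, config.ar1_rho)
        )
        sids.append(row["station_id"])
        years_list.append(yrs)
        dates_list.append([_season_days(y, row["sow_doy"], n_days) for y in yrs])
    return _assemble_daily(sids, years_list, dates_list, blocks)


def _decade_predictors(daily: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Decade-mean season predictors per station, joined with SOM."""
    from .agroclimate import aggregate_seasons

    feats = aggregate_seasons(daily)
    dec = feats.groupby("station_id", as_index=False)[
        ["tmin_mean", "tmax_mean", "prec_sum", "radn_sum", "gdd_sum"]
    ].mean()
    return dec.merge(stations[["station_id", "som", "region"]], on="station_id")


def generate_stations(
    config: SynthConfig = SynthConfig(), surface: TruthSurface = TruthSurface()
) -> SyntheticStations:
    """Stations across four regions with observed baseline-decade weather.

    Farmer densities sit 15–30% below the station's truth optimum and
    farmer yields at 48–56% of the attainable yield, emulating the density
    and yield gaps of current practice.
    """
    full = _station_frame(config)
    y0, y1 = config.baseline_years
    daily = _station_daily(full, range(y0, y1 + 1), config, stream=2)
    preds = _decade_predictors(daily, full)
    preds = preds.set_index("station_id").loc[full["station_id"]].reset_index()
    opd_true = surface.opd(preds)
    yield_true = surface.yield_at_opd(opd_true)
    rng = _rng(config.seed, 3)
    stations = full.assign(
        farmer_density=opd_true * rng.uniform(0.70, 0.85, len(full)),
        farmer_yield=yield_true * rng.uniform(0.48, 0.56, len(full)),
    )
    truth = pd.DataFrame(
        dict(station_id=stations["station_id"], opd_true=opd_true, yield_opd_true=yield_true)
    )
    # the hidden climate offsets are re-derivable from the seed; the public
    # table carries only what the real station schema would
    stations = stations.drop(columns=["tmin_off", "tmax_off", "radn_off", "prec_factor"])
    return SyntheticStations(
        stations=stations, daily=daily, truth=truth, config=config, surface=surface
    )


def generate_trials(
    synth: SyntheticStations,
    config: Optional[SynthConfig] = None,
    yield_noise_sd: Optional[float] = None,
) -> tuple[list[DensityTrial], pd.DataFrame, pd.DataFrame]:
    """Multi-density trials (site × year × hybrid) with known optima.

    Each sampled site-year gets one weather realization shared by 1–3
    hybrid-level trials; each trial's yields follow a concave quadratic
    whose vertex is the truth-surface optimum plus a small hybrid effect,
    with Gaussian noise on yields. Returns (trials, per-trial truth,
    site-year daily weather in the station weather schema).
    """
    config = config or synth.config
    surface = synth.surface
    noise_sd = config.yield_noise_sd if yield_noise_sd is None else yield_noise_sd
    rng = _rng(config.seed, 4)
    full = _station_frame(config)
    stations = full.set_index("station_id")
    y0, y1 = config.baseline_years

    trials: list[DensityTrial] = []
    truth_rows = []
    sids, years_list, dates_list, blocks = [], [], [], []
    used: set[tuple[str, int]] = set()
    t = 0
    while len(trials) < config.n_trials:
        sid = str(rng.choice(stations.index.to_numpy()))
        year = int(rng.integers(y0, y1 + 1))
        if (sid, year) in used:
            continue
        used.add((sid, year))
        row = stations.loc[sid]
        clim = _CLIMATOLOGY[row["region"]]
        n_days = int(row["season_len"])
        wrng = _rng(config.seed, 5, len(used))
        block = _weather_block(
            wrng, clim, _offsets(row), 1, n_days, config.temp_noise_sd, config.ar1_rho
        )
        days = _season_days(year, int(row["sow_doy"]), n_days)
        sids.append(sid)
        years_list.append(np.array([year]))
        dates_list.append([days])
        blocks.append(block)

        w = {k: v[0] for k, v in block.items()}
        gdd = daily_gdd(w["tmax"], w["tmin"])
        som = float(np.clip(row["som"] + rng.normal(0.0, 1.0), 1.0, 45.0))
        pred = pd.DataFrame(
            [dict(
                tmin_mean=float(np.mean(w["tmin"])), tmax_mean=float(np.mean(w["tmax"])),
                prec_sum=float(np.sum(w["prec"])), radn_sum=float(np.sum(w["radn"])),
                gdd_sum=float(np.sum(gdd)), som=som,
            )]
        )
        base_opd = float(surface.opd(pred)[0])
        n_hybrids = int(rng.integers(1, 4))
        for h in range(n_hybrids):
            if len(trials) >= config.n_trials:
                break
            t += 1
            opd_true = base_opd + float(rng.normal(0.0, config.hybrid_opd_sd))
            yopd_true = float(surface.yield_at_opd(opd_true) + rng.normal(0.0, 0.2))
            curvature = float(rng.uniform(-0.25, -0.10))
            n_levels = int(rng.integers(4, 7))
            span = rng.uniform(2.0, 3.0)
            dens = opd_true + np.linspace(-span, span, n_levels)
            dens = np.maximum(dens + rng.uniform(-0.15, 0.15, n_levels), 0.5)
            yields = yopd_true + curvature * (dens - opd_true) ** 2
            yields = np.maximum(yields + rng.normal(0.0, noise_sd, n_levels), 0.0)
            trial_id = f"T{t:04d}"
            sowing = days[0].astype("datetime64[D]").astype(date)
            maturity = days[-1].astype("datetime64[D]").astype(date)
            trials.append(
                DensityTrial(
                    trial_id=trial_id, site_id=sid, region=str(row["region"]),
                    year=year, hybrid=f"H{h + 1}", densities=dens, yields=yields,
                    som=som, sowing=sowing, maturity=maturity, water_regime="adequate",
                )
            )
            truth_rows.append(
                dict(trial_id=trial_id, opd_true=opd_true, yield_opd_true=yopd_true,
                     curvature=curvature, region=str(row["region"]))
            )
    weather = _assemble_daily(sids, years_list, dates_list, blocks)
    return trials, pd.DataFrame(truth_rows), weather


def generate_future_climate(
    synth: SyntheticStations,
    config: Optional[SynthConfig] = None,
    decades: tuple = ((2010, 2019), (2030, 2039)),
) -> Iterator[tuple[str, pd.DataFrame]]:
    """Lazily yield (gcm_id, season-window daily weather) per member.

    Each member draws its warming delta (the Tmin/Tmax shift reached by
    the future decade) and a precipitation scaling factor, generates one
    stochastic decade block of weather per station, and reuses that block
    in every decade with the member trend ramped on top. Decade contrasts
    therefore isolate the imposed trend: with a zero delta the decades
    are identical.
    """
    config = config or synth.config
    full = _station_frame(config)
    member_rng = _rng(config.seed, 6)
    deltas = member_rng.normal(
        config.warming_delta_mean, config.warming_delta_sd, config.n_gcms
    )
    prec_scales = member_rng.normal(1.0, config.prec_scale_sd, config.n_gcms)
    base_mid = (decades[0][0] + decades[0][1]) / 2.0
    future_mid = (decades[-1][0] + decades[-1][1]) / 2.0
    span = future_mid - base_mid or 1.0  # single decade → no trend to ramp

    for g in range(config.n_gcms):
        gcm_id = f"GCM{g + 1:02d}"
        sids, years_list, dates_list, blocks = [], [], [], []
        for idx, row in full.iterrows():
            clim = _CLIMATOLOGY[row["region"]]
            rng = _rng(config.seed, 7, g, idx)
            n_days = int(row["season_len"])
            base = _weather_block(
                rng, clim, _offsets(row), 10, n_days,
                config.temp_noise_sd, config.ar1_rho,
            )
            for d0, d1 in decades:
                years = np.arange(d0, d1 + 1)
                # linear ramp: zero at the baseline decade mid-point, full
                # member delta at the future decade mid-point
                ramp = ((years - base_mid) / span)[:, None]
                warmed = dict(
                    tmax=base["tmax"] + deltas[g] * ramp,
                    tmin=base["tmin"] + deltas[g] * ramp,
                    prec=base["prec"] * np.maximum(1.0 + (prec_scales[g] - 1.0) * ramp, 0.0),
                    radn=base["radn"],
                )
                sids.append(row["station_id"])
                years_list.append(years)
                dates_list.append(
                    [_season_days(y, row["sow_doy"], n_days) for y in years]
                )
                blocks.append(warmed)
        yield gcm_id, _assemble_daily(sids, years_list, dates_list, blocks)


def generate_national_history(
    config: SynthConfig = SynthConfig(),
    years: range = range(2000, 2020),
    density_slope: float = 0.05,  # 10⁴ plants ha⁻¹ per year
    yield_slope: float = 0.085,   # Mg ha⁻¹ per year
) -> pd.DataFrame:
    """National annual farmer density and yield with linear historical trends."""
    rng = _rng(config.seed, 8)
    yrs = np.array(list(years), dtype=float)
    density = 6.05 + density_slope * (yrs - 2015) + rng.normal(0.0, 0.05, len(yrs))
    yld = 6.0 + yield_slope * (yrs - 2015) + rng.normal(0.0, 0.15, len(yrs))
    return pd.DataFrame(dict(year=yrs.astype(int), density=density, yield_mg_ha=yld))


def generate_field_trials(
    synth: SyntheticStations, n_sites: int = 87, improvement: float = 0.21
) -> pd.DataFrame:
    """Paired control / optimum-treatment site results for the comparison report.

    Control plants the farmer density and yields ``improvement`` below the
    optimum treatment, which plants at the station's truth optimum.
    """
    config = synth.config
    rng = _rng(config.seed, 9)
    pool = synth.stations.merge(synth.truth, on="station_id")
    pool = pool[pool["region"].isin(["NE", "NCP", "SW"])]
    pick = pool.sample(n=min(n_sites, len(pool)), random_state=int(rng.integers(2**31)))
    ot_density = pick["opd_true"].to_numpy() + rng.normal(0.0, 0.3, len(pick))
    ot_yield = synth.surface.yield_at_opd(ot_density) + rng.normal(0.0, 0.4, len(pick))
    return pd.DataFrame(
        dict(
            site_id=pick["station_id"].to_numpy(),
            region=pick["region"].to_numpy(),
            ck_density=pick["farmer_density"].to_numpy(),
            ck_yield=ot_yield / (1.0 + improvement) + rng.normal(0.0, 0.3, len(pick)),
            ot_density=ot_density,
            ot_yield=ot_yield,
        )
    )


def write_truth(synth: SyntheticStations, trial_truth: pd.DataFrame, path: str | Path) -> None:
    """Persist the generative truth (tests only; the pipeline never reads it)."""
    payload = dict(
        surface=dict(
            intercept=synth.surface.intercept, coef=synth.surface.coef,
            som_knot=synth.surface.som_knot, opd_range=list(synth.surface.opd_range),
            yield_alpha=synth.surface.yield_alpha, yield_beta=synth.surface.yield_beta,
        ),
        config=asdict(synth.config),
        stations=synth.truth.to_dict(orient="list"),
        trials=trial_truth.to_dict(orient="list"),
    )
    Path(path).write_text(json.dumps(payload, indent=1))
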