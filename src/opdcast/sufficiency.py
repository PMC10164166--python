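"""National maize demand/supply accounting and the self-sufficiency verdict.

Apparent domestic demand = production + imports − exports − stock change
(ending minus beginning stocks), averaged over the baseline years; dividing
by the baseline population gives per-capita demand (kg person⁻¹ yr⁻¹),
held constant to project total demand at a target population. Supply is
harvested area × projected yield. All national masses are in Mt (10⁶ t);
yields in Mg ha⁻¹; areas in ha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "DemandSpec",
    "SupplyProjection",
    "Verdict",
    "baseline_per_capita_demand",
    "project_demand",
    "supply_from_area_yield",
    "assess_sufficiency",
]


@dataclass(frozen=True)
class DemandSpec:
    """Baseline supply-utilization accounts and population path."""

    production: float        # Mt, baseline average
    imports: float           # Mt
    exports: float           # Mt
    stock_change: float      # Mt, ending minus beginning stocks (may be < 0)
    population_base: float   # persons
    population_target: float  # persons
    target_year: int = 2035

    def __post_init__(self) -> None:
        for name in ("production", "imports", "exports"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.population_base <= 0 or self.population_target <= 0:
            raise ValueError("populations must be positive")


@dataclass(frozen=True)
class SupplyProjection:
    """Projected national production from per-region area × yield."""

    area_ha: Mapping[str, float]
    yield_mg_ha: Mapping[str, float]
    production_mt: float

    def __post_init__(self) -> None:
        check = sum(self.area_ha[r] * self.yield_mg_ha[r] for r in self.area_ha) / 1e6
        if abs(check - self.production_mt) > 1e-9 * max(1.0, abs(check)):
            raise ValueError("production inconsistent with area × yield")


@dataclass(frozen=True)
class Verdict:
    ratio: float
    self_sufficient: bool
    surplus_mt: float
    demand_mt: float
    production_mt: float


def baseline_per_capita_demand(spec: DemandSpec) -> tuple[float, float]:
    """Baseline national demand (Mt) and per-capita demand (kg/person/yr)."""
    demand_mt = spec.production + spec.imports - spec.exports - spec.stock_change
    if demand_mt < 0:
        raise ValueError(f"computed baseline demand is negative: {demand_mt:.3f} Mt")
    per_capita_kg = demand_mt * 1e9 / spec.population_base
    return demand_mt, per_capita_kg


def project_demand(per_capita_kg: float, population: float) -> float:
    """Total demand (Mt) at constant per-capita consumption."""
    if per_capita_kg < 0 or population <= 0:
        raise ValueError("per-capita demand must be ≥ 0 and population > 0")
    return per_capita_kg * population / 1e9


def supply_from_area_yield(
    area_ha: Mapping[str, float], yield_mg_ha: Mapping[str, float]
) -> SupplyProjection:
    """National production (Mt) from per-region harvested area and yield."""
    if set(area_ha) != set(yield_mg_ha):
        raise ValueError("area and yield must cover the same regions")
    production = sum(area_ha[r] * yield_mg_ha[r] for r in area_ha) / 1e6
    return SupplyProjection(
        area_ha=dict(area_ha), yield_mg_ha=dict(yield_mg_ha), production_mt=production
    )


def assess_sufficiency(production_mt: float, demand_mt: float) -> Verdict:
    """Self-sufficiency ratio; ≥ 1 means demand is fully met domestically."""
    if demand_mt <= 0:
        raise ValueError("demand must be positive")
    ratio = production_mt / demand_mt
    return Verdict(
        ratio=ratio,
        self_sufficient=ratio >= 1.0,
        surplus_mt=production_mt - demand_mt,
        demand_mt=demand_mt,
        production_mt=production_mt,
    )
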