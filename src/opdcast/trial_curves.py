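"""Yield–density curve fitting and optimum-density extraction.

Multi-density field trials are screened (adequate water supply, enough
distinct density levels), a concave quadratic yield = a + b·d + c·d² is
fitted per trial, and the vertex gives the optimum plant density (OPD,
10⁴ plants ha⁻¹) and the yield at that density (Yield_OPD, Mg ha⁻¹).
A linear relation Yield_OPD = α + β·OPD is then fitted across trials so
that projected densities can be mapped to attainable yields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .agroclimate import SeasonPredictors

logger = logging.getLogger(__name__)

__all__ = [
    "REGIONS",
    "DensityTrial",
    "QuadraticFit",
    "OPDRecord",
    "LinearYieldModel",
    "DegenerateDesignError",
    "screen_trials",
    "fit_yield_density_curve",
    "default_density_window",
    "extract_optimum",
    "fit_opd_yield_relation",
]

REGIONS = ("NE", "NCP", "NW", "SW")

#: Default admissible-OPD window as multiples of (min, max) observed density.
WINDOW_FACTORS = (0.5, 1.2)


class DegenerateDesignError(ValueError):
    """Fewer distinct design points than parameters to estimate."""


@dataclass
class DensityTrial:
    """One site × year × hybrid multi-density trial."""

    trial_id: str
    site_id: str
    region: str
    year: int
    hybrid: str
    densities: np.ndarray  # 10⁴ plants ha⁻¹
    yields: np.ndarray     # Mg ha⁻¹
    som: float             # g kg⁻¹
    sowing: date
    maturity: date
    water_regime: str = "adequate"
    predictors: Optional[SeasonPredictors] = None

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.densities.shape != self.yields.shape:
            raise ValueError("densities and yields must have equal length")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be strictly positive")
        if np.any(self.yields < 0):
            raise ValueError("yields must be non-negative")
        if not self.sowing < self.maturity:
            raise ValueError("sowing date must precede maturity date")
        if self.water_regime not in ("adequate", "deficit"):
            raise ValueError(f"unknown water regime {self.water_regime!r}")

    @property
    def n_distinct_levels(self) -> int:
        # replicates at the same density count once for screening
        return int(np.unique(self.densities).size)


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares coefficients of yield = a + b·d + c·d²."""

    a: float
    b: float
    c: float
    r2: float
    n_points: int


@dataclass
class OPDRecord:
    """Vertex of one fitted trial curve: the (OPD, Yield_OPD) pair."""

    trial_id: str
    opd: float
    yield_opd: float
    valid: bool
    reason: str = ""
    predictors: Optional[SeasonPredictors] = None
    region: str = ""
    fit: Optional[QuadraticFit] = None


@dataclass(frozen=True)
class LinearYieldModel:
    """OLS relation Yield_OPD = alpha + beta·OPD across valid trials."""

    alpha: float
    beta: float
    r2: float
    ci95: float  # half-width of the 95% CI on beta
    n: int

    def predict(self, opd):
        return self.alpha + self.beta * np.asarray(opd, dtype=float)


def screen_trials(
    trials: Sequence[DensityTrial], min_levels: int = 4
) -> list[DensityTrial]:
    """Keep trials with ≥ ``min_levels`` distinct densities and adequate water.

    Input order is preserved; each rejection is logged with its reason.
    """
    if min_levels < 3:
        raise ValueError("min_levels must be at least 3 (quadratic needs 3 points)")
    if len(trials) == 0:
        logger.warning("screen_trials called with no trials")
        return []
    kept: list[DensityTrial] = []
    for t in trials:
        if t.water_regime != "adequate":
            logger.info("trial %s rejected: water regime %r", t.trial_id, t.water_regime)
        elif t.n_distinct_levels < min_levels:
            logger.info(
                "trial %s rejected: %d distinct density levels < %d",
                t.trial_id, t.n_distinct_levels, min_levels,
            )
        else:
            kept.append(t)
    logger.info("screening kept %d of %d trials", len(kept), len(trials))
    return kept


def _fit_quadratic(d: np.ndarray, y: np.ndarray) -> QuadraticFit:
    if np.unique(d).size < 3:
        raise DegenerateDesignError(
            f"need ≥3 distinct densities to fit a quadratic, got {np.unique(d).size}"
        )
    design = np.column_stack([np.ones_like(d), d, d * d])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return QuadraticFit(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        r2=min(1.0, r2), n_points=int(d.size),
    )


def fit_yield_density_curve(trial: DensityTrial) -> QuadraticFit:
    """Fit the quadratic yield–density response for one trial.

    Replicated densities are allowed in the fit; a degenerate design
    (fewer than 3 distinct levels) raises :class:`DegenerateDesignError`.
    """
    return _fit_quadratic(trial.densities, trial.yields)


def default_density_window(densities: np.ndarray) -> tuple[float, float]:
    """Admissible window for the vertex: [0.5·min(d), 1.2·max(d)].

    Rejects optima that would be extreme extrapolations beyond the
    densities actually evaluated.
    """
    d = np.asarray(densities, dtype=float)
    return (WINDOW_FACTORS[0] * float(d.min()), WINDOW_FACTORS[1] * float(d.max()))


def extract_optimum(
    fit: QuadraticFit,
    density_window: tuple[float, float],
    trial_id: str = "",
    predictors: Optional[SeasonPredictors] = None,
    region: str = "",
) -> OPDRecord:
    """Vertex of the fitted parabola: OPD = −b/2c, Yield_OPD = a − b²/4c.

    The record is valid only for a concave fit (c < 0) whose vertex lies
    inside ``density_window``; otherwise it is returned flagged invalid
    with a reason, never raised.
    """
    lo, hi = density_window
    common = dict(trial_id=trial_id, predictors=predictors, region=region, fit=fit)
    if fit.c >= 0:
        return OPDRecord(opd=np.nan, yield_opd=np.nan, valid=False,
                         reason="no interior maximum", **common)
    opd = -fit.b / (2.0 * fit.c)
    yield_opd = fit.a - fit.b**2 / (4.0 * fit.c)
    if not (lo <= opd <= hi):
        return OPDRecord(opd=float(opd), yield_opd=float(yield_opd), valid=False,
                         reason=f"vertex {opd:.2f} outside window [{lo:.2f}, {hi:.2f}]",
                         **common)
    if opd <= 0 or yield_opd <= 0:
        return OPDRecord(opd=float(opd), yield_opd=float(yield_opd), valid=False,
                         reason="non-positive optimum", **common)
    return OPDRecord(opd=float(opd), yield_opd=float(yield_opd), valid=True, **common)


def fit_opd_yield_relation(records: Sequence[OPDRecord]) -> LinearYieldModel:
    """OLS of Yield_OPD on OPD over the valid records.

    Returns slope, intercept, r², and the 95% confidence half-width of
    the slope (Student t). Invalid records are excluded and counted in
    the log.
    """
    valid = [r for r in records if r.valid]
    n_dropped = len(records) - len(valid)
    if n_dropped:
        logger.info("fit_opd_yield_relation: excluded %d invalid record(s)", n_dropped)
    if len(valid) < 3:
        raise ValueError(f"need ≥3 valid records, got {len(valid)}")
    x = np.array([r.opd for r in valid])
    y = np.array([r.yield_opd for r in valid])
    if np.all(x == x[0]):
        raise DegenerateDesignError("all OPD values identical; slope not identifiable")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    return LinearYieldModel(
        alpha=float(res.intercept),
        beta=float(res.slope),
        r2=float(res.rvalue**2),
        ci95=float(tcrit * res.stderr),
        n=len(x),
    )
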