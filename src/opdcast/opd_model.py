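"""Random-forest surrogate for optimum plant density (the OPD-RF model).

The surrogate regresses trial-level OPD on six growing-season predictors
(mean Tmin, mean Tmax, summed precipitation, summed radiation, summed GDD,
SOM). Hyperparameters follow common random-forest defaults for this kind
of agronomic regression: 500 trees, 3 candidate predictors per split.

Evaluation metrics: R² is the squared Pearson correlation between
observed and simulated values; RMSE is the root mean squared error; RRMSE
is RMSE divided by the observed mean, in percent. Variable importance is
permutation importance (increase in MSE when one predictor is shuffled),
floored at zero and scaled to sum to 100% within each region; the sign
and significance of each driver come from the univariate OLS slope of OPD
on that driver within the region.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .trial_curves import OPDRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "TARGET",
    "FeatureMatrix",
    "TrainedModel",
    "EvalReport",
    "PartialResponse",
    "build_feature_matrix",
    "feature_schema_hash",
    "train_opd_model",
    "split_train_eval",
    "evaluate_predictions",
    "loo_evaluate",
    "variable_importance",
    "partial_response",
    "estimate_som_plateau",
]

#: Fixed predictor column order of the feature matrix.
FEATURES = ("tmin_mean", "tmax_mean", "prec_sum", "radn_sum", "gdd_sum", "som")
TARGET = "opd"

#: A feature matrix is a DataFrame with the six FEATURES columns plus the
#: ``opd`` target; extra columns (region, trial_id) are carried along.
FeatureMatrix = pd.DataFrame


def feature_schema_hash(columns: Sequence[str] = FEATURES) -> str:
    return hashlib.sha256("|".join(columns).encode()).hexdigest()[:16]


def build_feature_matrix(records: Sequence[OPDRecord]) -> FeatureMatrix:
    """Assemble the training table from valid OPD records."""
    rows = []
    for r in records:
        if not r.valid:
            continue
        if r.predictors is None:
            raise ValueError(f"record {r.trial_id} has no season predictors")
        p = r.predictors
        rows.append(
            dict(
                trial_id=r.trial_id, region=r.region,
                tmin_mean=p.tmin_mean, tmax_mean=p.tmax_mean,
                prec_sum=p.prec_sum, radn_sum=p.radn_sum,
                gdd_sum=p.gdd_sum, som=p.som,
                opd=r.opd, yield_opd=r.yield_opd,
            )
        )
    if not rows:
        raise ValueError("no valid records to build a feature matrix from")
    return pd.DataFrame(rows)


def _check_features(data: pd.DataFrame, require_target: bool = True) -> None:
    missing_cols = [c for c in FEATURES if c not in data.columns]
    if require_target and TARGET not in data.columns:
        missing_cols.append(TARGET)
    if missing_cols:
        raise ValueError(f"feature matrix missing columns: {missing_cols}")
    cols = list(FEATURES) + ([TARGET] if require_target else [])
    na = data[cols].isna()
    if na.to_numpy().any():
        bad_rows = data.index[na.any(axis=1)].tolist()[:10]
        bad_cols = na.columns[na.any(axis=0)].tolist()
        raise ValueError(f"missing values in columns {bad_cols}, rows {bad_rows}")


@dataclass
class TrainedModel:
    """Fitted ensemble plus the metadata needed for safe reuse."""

    estimator: RandomForestRegressor
    n_trees: int
    m_try: int
    seed: int
    schema_hash: str = field(default_factory=feature_schema_hash)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        if feature_schema_hash(FEATURES) != self.schema_hash:
            raise ValueError("feature schema does not match the trained model")
        _check_features(data, require_target=False)
        return self.estimator.predict(data[list(FEATURES)].to_numpy())

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def train_opd_model(
    data: FeatureMatrix,
    n_trees: int = 500,
    m_try: int = 3,
    seed: int = 42,
    min_rows: int = 30,
) -> TrainedModel:
    """Fit the random-forest density surrogate.

    Deterministic under a fixed ``seed``. ``m_try`` is the number of
    candidate predictors considered at each split.
    """
    _check_features(data)
    if len(data) < min_rows:
        raise ValueError(f"need ≥{min_rows} rows to train, got {len(data)}")
    est = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=m_try,
        random_state=seed,
        n_jobs=1,
        oob_score=False,
    )
    est.fit(data[list(FEATURES)].to_numpy(), data[TARGET].to_numpy())
    return TrainedModel(estimator=est, n_trees=n_trees, m_try=m_try, seed=seed)


def split_train_eval(
    data: FeatureMatrix, fraction: float = 0.8, seed: int = 42
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Random, reproducible train/test partition (disjoint and exhaustive)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(data)
    if n < 5:
        raise ValueError(f"refusing to split fewer than 5 rows (got {n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    return data.iloc[order[:n_train]].copy(), data.iloc[order[n_train:]].copy()


@dataclass(frozen=True)
class EvalReport:
    """Skill metrics for observed vs simulated values.

    r2 / rrmse are NaN when undefined (zero variance, zero observed mean),
    with the matching flag set.
    """

    r2: float
    rmse: float
    rrmse: float  # percent
    n: int
    protocol: str = "holdout_80_20"
    r2_defined: bool = True
    rrmse_defined: bool = True


def evaluate_predictions(
    obs, sim, protocol: str = "holdout_80_20", as_printed: bool = False
) -> EvalReport:
    """Compute R², RMSE and RRMSE (%) for paired observed/simulated values.

    R² is the squared Pearson correlation. ``as_printed`` switches to an
    audit variant that centres the simulated values on the observed mean
    inside the denominator instead of their own mean.
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape or obs.size < 2:
        raise ValueError("obs and sim must be equal-length vectors of size ≥ 2")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    o_mean = float(obs.mean())
    rrmse_defined = o_mean != 0
    rrmse = rmse / o_mean * 100.0 if rrmse_defined else float("nan")

    do = obs - obs.mean()
    ds = sim - (obs.mean() if as_printed else sim.mean())
    denom = np.sqrt(np.sum(do**2)) * np.sqrt(np.sum(ds**2))
    r2_defined = denom > 0
    r2 = float((np.sum(do * ds) / denom) ** 2) if r2_defined else float("nan")
    return EvalReport(
        r2=r2, rmse=rmse, rrmse=rrmse, n=obs.size, protocol=protocol,
        r2_defined=bool(r2_defined), rrmse_defined=bool(rrmse_defined),
    )


def loo_evaluate(
    data: FeatureMatrix, n_trees: int = 500, m_try: int = 3, seed: int = 42
) -> EvalReport:
    """Leave-one-out skill: n refits, each predicting its held-out row."""
    _check_features(data)
    n = len(data)
    if n < 10:
        raise ValueError(f"leave-one-out needs ≥10 rows, got {n}")
    X = data[list(FEATURES)].to_numpy()
    y = data[TARGET].to_numpy()
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = RandomForestRegressor(
            n_estimators=n_trees, max_features=m_try, random_state=seed, n_jobs=1
        )
        est.fit(X[mask], y[mask])
        preds[i] = est.predict(X[i : i + 1])[0]
    return evaluate_predictions(y, preds, protocol="leave_one_out")


def variable_importance(
    model: TrainedModel,
    data: FeatureMatrix,
    region_col: str = "region",
    n_repeats: int = 10,
    seed: int = 42,
    min_region_rows: int = 10,
) -> pd.DataFrame:
    """Per-region permutation importance, scaled to sum to 100%.

    For each region the increase in MSE when one predictor is permuted is
    averaged over ``n_repeats`` shuffles, negatives are floored at zero,
    and the six values are rescaled to sum to 100. The sign column is the
    sign of the within-region univariate OLS slope of OPD on the
    predictor; p_value is that slope's two-sided t-test. Regions with
    fewer than ``min_region_rows`` rows are skipped with a warning.
    """
    _check_features(data)
    if region_col not in data.columns:
        raise ValueError(f"data has no {region_col!r} column")
    rows = []
    for region, grp in data.groupby(region_col, sort=True):
        if len(grp) < min_region_rows:
            logger.warning(
                "region %s skipped: %d rows < %d", region, len(grp), min_region_rows
            )
            continue
        X = grp[list(FEATURES)]
        y = grp[TARGET].to_numpy()
        pi = permutation_importance(
            model.estimator,
            X.to_numpy(),
            y,
            scoring="neg_mean_squared_error",
            n_repeats=n_repeats,
            random_state=seed,
        )
        raw = np.maximum(pi.importances_mean, 0.0)
        total = raw.sum()
        scaled = raw / total * 100.0 if total > 0 else np.full(len(FEATURES), 100.0 / len(FEATURES))
        for j, feat in enumerate(FEATURES):
            x = grp[feat].to_numpy()
            if np.ptp(x) == 0:
                sign, pval = "+", float("nan")
            else:
                res = stats.linregress(x, y)
                sign = "+" if res.slope >= 0 else "-"
                pval = float(res.pvalue)
            rows.append(
                dict(region=region, predictor=feat,
                     importance_pct=float(scaled[j]), sign=sign, p_value=pval)
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PartialResponse:
    """Best simple functional form of OPD against one driver."""

    driver: str
    form: str               # "linear" or "quadratic"
    coefficients: tuple     # ascending powers
    slope_at_mean: float    # per-unit effect at the driver's data mean
    adj_r2: float
    n: int


def _poly_adj_r2(x: np.ndarray, y: np.ndarray, degree: int):
    design = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    n, p = len(x), degree
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return coef, adj


def partial_response(
    data: pd.DataFrame, driver: str, region: Optional[str] = None
) -> PartialResponse:
    """Fit linear and quadratic OPD–driver curves; keep the better one.

    Selection is by adjusted R². The per-unit effect reported is the
    derivative of the selected curve at the driver's data mean.
    """
    if driver not in FEATURES:
        raise ValueError(f"unknown driver {driver!r}")
    sub = data if region is None else data[data["region"] == region]
    if len(sub) < 10:
        raise ValueError(f"need ≥10 records, got {len(sub)}")
    x = sub[driver].to_numpy(dtype=float)
    y = sub[TARGET].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"driver {driver!r} has zero variance")
    lin_coef, lin_adj = _poly_adj_r2(x, y, 1)
    quad_coef, quad_adj = _poly_adj_r2(x, y, 2)
    if quad_adj > lin_adj:
        form, coef, adj = "quadratic", quad_coef, quad_adj
        slope = float(coef[1] + 2.0 * coef[2] * x.mean())
    else:
        form, coef, adj = "linear", lin_coef, lin_adj
        slope = float(coef[1])
    return PartialResponse(
        driver=driver, form=form, coefficients=tuple(float(c) for c in coef),
        slope_at_mean=slope, adj_r2=float(adj), n=len(x),
    )


def estimate_som_plateau(
    data: FeatureMatrix,
    knot_grid: Optional[np.ndarray] = None,
    adjust_for_climate: bool = True,
) -> tuple[float, float]:
    """Locate the SOM level beyond which OPD stops responding.

    Fits OPD ~ [climate predictors +] min(SOM, k) by OLS for each
    candidate knot k and returns (best knot, slope below the knot), the
    knot chosen by minimum residual sum of squares. Adjusting for the
    climate predictors sharpens the profile because they explain most of
    the non-SOM variance.
    """
    _check_features(data)
    if knot_grid is None:
        knot_grid = np.arange(8.0, 32.0 + 1e-9, 0.25)
    som = data["som"].to_numpy(dtype=float)
    y = data[TARGET].to_numpy(dtype=float)
    others = [f for f in FEATURES if f != "som"]
    base = (
        np.column_stack([np.ones(len(y))] + [data[f].to_numpy(dtype=float) for f in others])
        if adjust_for_climate
        else np.ones((len(y), 1))
    )
    best = (np.inf, float("nan"), float("nan"))
    for k in knot_grid:
        design = np.column_stack([base, np.minimum(som, k)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss = float(resid @ resid)
        if ss < best[0]:
            best = (ss, float(k), float(coef[-1]))
    return best[1], best[2]
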