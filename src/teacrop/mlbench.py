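"""Ten-regressor yield benchmark on plot-level plucking records.

Features are the meteorological factors attached to each plucking
sample (tmin, tmax, mean relative humidity, rainfall) plus a binary
green/black tea indicator; the target is observed yield converted from
kg per one-acre plot to t/ha. Two protocols are provided: a seeded
70/30 train-test split and seeded 10-fold cross-validation with
unweighted fold averaging. Errors are MAE, MSE and RMSE:

    MAE  = (1/n) sum |y_j - yhat_j|
    MSE  = (1/n) sum (y_j - yhat_j)^2
    RMSE = sqrt(MSE)

Eight of the ten regressors delegate to scikit-learn / xgboost with the
benchmark's fixed hyperparameters; simple linear regression (SLR, one
predictor) is a direct closed-form ordinary-least-squares fit and
multiple linear regression is also available as a normal-equations
cross-check.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor
from sklearn.linear_model import ARDRegression, LinearRegression, RANSACRegressor
from sklearn.model_selection import KFold, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR, LinearSVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .teasim import KG_PER_ACRE_TO_T_HA

__all__ = [
    "PlotSample",
    "ModelSpec",
    "EvalResult",
    "mae",
    "mse",
    "rmse",
    "build_feature_table",
    "fit_slr",
    "fit_mlr_normal_equations",
    "train_test_evaluate",
    "kfold_evaluate",
    "run_benchmark",
    "compare_with_simulation",
    "default_model_specs",
    "read_samples_csv",
    "samples_to_frame",
    "MODEL_NAMES",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["tmin", "tmax", "rh_mean", "rain", "tea_type_green"]

MODEL_NAMES = ("LinearSVR", "AdaBoost", "ARD", "DecisionTree", "MLP",
               "MLR", "RANSAC", "SLR", "XGBoost", "SVR")


@dataclass(frozen=True)
class PlotSample:
    """One plot-level plucking record (plot size: one acre).

    yield_obs is the plucked quantity in kg for that plot and day.
    """

    plot_id: str
    date: _dt.date
    tea_type: str
    tmin: float
    tmax: float
    rh_mean: float
    rain: float
    yield_obs: float

    def __post_init__(self) -> None:
        if self.tea_type not in ("green", "black"):
            raise ValueError(f"tea_type must be 'green' or 'black', got {self.tea_type!r}")
        if self.yield_obs < 0:
            raise ValueError("yield_obs must be non-negative")
        for name in ("tmin", "tmax", "rh_mean", "rain"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite feature {name}")


# ---------------------------------------------------------------------------
# error metrics


def mae(y_obs: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean absolute error."""
    a, b = _as_pair(y_obs, y_pred)
    return float(np.mean(np.abs(a - b)))


def mse(y_obs: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean squared error."""
    a, b = _as_pair(y_obs, y_pred)
    return float(np.mean((a - b) ** 2))


def rmse(y_obs: Sequence[float], y_pred: Sequence[float]) -> float:
    """Root mean squared error, sqrt(MSE)."""
    return math.sqrt(mse(y_obs, y_pred))


def _as_pair(y_obs, y_pred) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_obs, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError(f"vectors must have equal nonzero length, got {a.shape} vs {b.shape}")
    return a, b


@dataclass(frozen=True)
class EvalResult:
    """An (MAE, MSE, RMSE) triple for one named method under one protocol.

    MAE and RMSE are in t/ha, MSE in (t/ha)^2.
    """

    method: str
    protocol: Literal["train_test", "cv10", "simulation"]
    mae: float
    mse: float
    rmse: float

    def __post_init__(self) -> None:
        if min(self.mae, self.mse, self.rmse) < 0:
            raise ValueError("error metrics must be non-negative")


# ---------------------------------------------------------------------------
# feature table


def build_feature_table(samples: Sequence[PlotSample],
                        include_tea_type: bool = True
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and t/ha target vector from plucking samples.

    Features: [tmin, tmax, rh_mean, rain, tea_type_green (1=green,
    0=black)]; target: yield_obs converted kg/acre -> t/ha. Row order
    is preserved and duplicates are kept.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    rows = []
    target = []
    for i, s in enumerate(samples):
        if not isinstance(s, PlotSample):
            raise ValueError(f"row {i}: not a PlotSample")
        row = {"tmin": s.tmin, "tmax": s.tmax, "rh_mean": s.rh_mean,
               "rain": s.rain}
        if include_tea_type:
            row["tea_type_green"] = 1.0 if s.tea_type == "green" else 0.0
        rows.append(row)
        target.append(s.yield_obs * KG_PER_ACRE_TO_T_HA)
    return pd.DataFrame(rows), np.array(target)


def read_samples_csv(path) -> list[PlotSample]:
    """Read plucking samples from CSV with columns
    ``plot_id, date, tea_type, tmin_c, tmax_c, rh_pct, rain_mm,
    yield_kg_acre``; rows with missing values are rejected with their
    index."""
    df = pd.read_csv(path)
    required = ["plot_id", "date", "tea_type", "tmin_c", "tmax_c",
                "rh_pct", "rain_mm", "yield_kg_acre"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"samples CSV missing columns: {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        if row[required].isna().any():
            raise ValueError(f"missing value in samples row {idx}")
        out.append(PlotSample(
            plot_id=str(row["plot_id"]),
            date=_dt.date.fromisoformat(str(row["date"])),
            tea_type=str(row["tea_type"]),
            tmin=float(row["tmin_c"]),
            tmax=float(row["tmax_c"]),
            rh_mean=float(row["rh_pct"]),
            rain=float(row["rain_mm"]),
            yield_obs=float(row["yield_kg_acre"]),
        ))
    return out


def samples_to_frame(samples: Sequence[PlotSample]) -> pd.DataFrame:
    """Samples as a DataFrame in the CSV column schema."""
    return pd.DataFrame([{
        "plot_id": s.plot_id,
        "date": s.date.isoformat(),
        "tea_type": s.tea_type,
        "tmin_c": s.tmin,
        "tmax_c": s.tmax,
        "rh_pct": s.rh_mean,
        "rain_mm": s.rain,
        "yield_kg_acre": s.yield_obs,
    } for s in samples])


# ---------------------------------------------------------------------------
# direct linear fits (oracle paths)


def fit_slr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Closed-form simple linear regression: returns (slope, intercept).

    Minimises the sum of squared errors for y = slope*x + intercept.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or xa.shape != ya.shape:
        raise ValueError("need >= 2 paired observations")
    xbar = xa.mean()
    sxx = float(np.sum((xa - xbar) ** 2))
    if sxx == 0.0:
        raise ValueError("zero variance in x")
    slope = float(np.sum((xa - xbar) * (ya - ya.mean())) / sxx)
    return slope, float(ya.mean() - slope * xbar)


def fit_mlr_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Multiple linear regression via the normal equations.

    Returns coefficients [intercept, b1, ..., bp]; used as an
    independent cross-check of the delegated linear model.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(Xa)), Xa])
    return np.linalg.solve(A.T @ A, A.T @ ya)


class _SLRModel:
    """Single-predictor OLS on the first feature column (tmin)."""

    def __init__(self) -> None:
        self.slope_ = 0.0
        self.intercept_ = 0.0

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)[:, 0]
        self.slope_, self.intercept_ = fit_slr(x, y)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)[:, 0]
        return self.slope_ * x + self.intercept_


# ---------------------------------------------------------------------------
# model registry


@dataclass(frozen=True)
class ModelSpec:
    """A named regressor with its fixed hyperparameters and seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        schema = _HYPERPARAM_SCHEMA[self.name]
        unknown = set(self.hyperparameters) - schema
        if unknown:
            raise ValueError(
                f"hyperparameters {sorted(unknown)} not in {self.name} schema")

    def build(self):
        """Instantiate the underlying estimator."""
        return _BUILDERS[self.name](self.hyperparameters, self.seed)


_HYPERPARAM_SCHEMA: dict[str, set] = {
    "LinearSVR": {"C", "epsilon", "tol", "max_iter"},
    "AdaBoost": {"n_estimators", "learning_rate", "loss"},
    "ARD": {"max_iter", "tol", "alpha_1", "alpha_2", "lambda_1", "lambda_2"},
    "DecisionTree": {"max_depth", "min_samples_split", "min_samples_leaf"},
    "MLP": {"hidden_layer_sizes", "activation", "max_iter", "alpha",
            "learning_rate_init"},
    "MLR": set(),
    "RANSAC": {"min_samples", "residual_threshold", "max_trials"},
    "SLR": set(),
    "XGBoost": {"colsample_bytree", "gamma", "learning_rate", "max_depth",
                "min_child_weight", "n_estimators", "reg_alpha", "reg_lambda",
                "subsample", "seed"},
    "SVR": {"kernel", "degree", "gamma", "coef0", "tol", "C", "epsilon",
            "shrinking", "cache_size", "max_iter"},
}

#: XGBoost hyperparameters fixed for the benchmark.
XGBOOST_PARAMS = dict(
    colsample_bytree=0.4, gamma=0, learning_rate=0.1, max_depth=20,
    min_child_weight=1.7, n_estimators=100, reg_alpha=0.75,
    reg_lambda=0.45, subsample=0.8, seed=50,
)


def _build_xgb(hp: dict, seed: int) -> XGBRegressor:
    params = dict(XGBOOST_PARAMS)
    params.update(hp)
    rs = params.pop("seed")
    return XGBRegressor(random_state=rs, n_jobs=1, **params)


_BUILDERS: dict[str, Callable] = {
    "LinearSVR": lambda hp, seed: LinearSVR(random_state=seed, **hp),
    "AdaBoost": lambda hp, seed: AdaBoostRegressor(
        estimator=DecisionTreeRegressor(random_state=seed),
        random_state=seed, **hp),
    "ARD": lambda hp, seed: ARDRegression(**hp),
    "DecisionTree": lambda hp, seed: DecisionTreeRegressor(
        random_state=seed, **{"max_depth": 20, **hp}),
    "MLP": lambda hp, seed: MLPRegressor(random_state=seed, **hp),
    "MLR": lambda hp, seed: LinearRegression(),
    "RANSAC": lambda hp, seed: RANSACRegressor(random_state=seed, **hp),
    "SLR": lambda hp, seed: _SLRModel(),
    "XGBoost": _build_xgb,
    "SVR": lambda hp, seed: SVR(**{"kernel": "rbf", **hp}),
}


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    """The ten benchmark regressors with their fixed configurations."""
    specs = []
    for name in MODEL_NAMES:
        hp = dict(XGBOOST_PARAMS) if name == "XGBoost" else {}
        specs.append(ModelSpec(name=name, hyperparameters=hp, seed=seed))
    return specs


# ---------------------------------------------------------------------------
# evaluation protocols


def _fit_predict(spec: ModelSpec, X_train, y_train, X_test) -> np.ndarray:
    import warnings

    model = spec.build()
    with warnings.catch_warnings():
        # small tables make iterative learners (MLP, LinearSVR) warn about
        # convergence; the fixed-budget fit is part of the protocol
        warnings.simplefilter("ignore")
        model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
        return np.asarray(model.predict(np.asarray(X_test, dtype=float)), dtype=float)


def train_test_evaluate(spec: ModelSpec, table: tuple[pd.DataFrame, np.ndarray],
                        train_frac: float = 0.70, split_seed: int = 42) -> EvalResult:
    """Seeded 70/30 split; metrics on the held-out 30%."""
    X, y = table
    if len(X) < 10:
        raise ValueError("need at least 10 rows")
    X_train, X_test, y_train, y_test = train_test_split(
        X.to_numpy(dtype=float), y, train_size=train_frac,
        random_state=split_seed, shuffle=True)
    pred = _fit_predict(spec, X_train, y_train, X_test)
    return EvalResult(method=spec.name, protocol="train_test",
                      mae=mae(y_test, pred), mse=mse(y_test, pred),
                      rmse=rmse(y_test, pred))


def kfold_evaluate(spec: ModelSpec, table: tuple[pd.DataFrame, np.ndarray],
                   k: int = 10, split_seed: int = 42) -> EvalResult:
    """Seeded k-fold cross-validation; unweighted mean of per-fold metrics."""
    X, y = table
    Xa = X.to_numpy(dtype=float)
    if len(Xa) < k:
        raise ValueError(f"need at least k={k} rows, got {len(Xa)}")
    kf = KFold(n_splits=k, shuffle=True, random_state=split_seed)
    maes, mses, rmses = [], [], []
    for train_idx, test_idx in kf.split(Xa):
        pred = _fit_predict(spec, Xa[train_idx], y[train_idx], Xa[test_idx])
        maes.append(mae(y[test_idx], pred))
        mses.append(mse(y[test_idx], pred))
        rmses.append(rmse(y[test_idx], pred))
    return EvalResult(method=spec.name, protocol="cv10",
                      mae=float(np.mean(maes)), mse=float(np.mean(mses)),
                      rmse=float(np.mean(rmses)))


def run_benchmark(table: tuple[pd.DataFrame, np.ndarray],
                  protocol: Literal["train_test", "cv10"] = "train_test",
                  model_seed: int = 0, split_seed: int = 42,
                  k: int = 10) -> list[EvalResult]:
    """Evaluate all ten registered regressors under one protocol.

    Returns results sorted by RMSE ascending (best first).
    """
    results = []
    for spec in default_model_specs(seed=model_seed):
        if protocol == "train_test":
            results.append(train_test_evaluate(spec, table, split_seed=split_seed))
        elif protocol == "cv10":
            results.append(kfold_evaluate(spec, table, k=k, split_seed=split_seed))
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
    return sorted(results, key=lambda r: r.rmse)


def compare_with_simulation(sim: EvalResult,
                            ml: Sequence[EvalResult]) -> pd.DataFrame:
    """Per-method (simulation minus ML) error differences.

    Positive entries mean the simulation's error exceeds the ML model's
    error for that metric (ML better).
    """
    rows = []
    for r in ml:
        rows.append({
            "method": r.method,
            "protocol": r.protocol,
            "mae_diff_t_ha": sim.mae - r.mae,
            "mse_diff_t_ha2": sim.mse - r.mse,
            "rmse_diff_t_ha": sim.rmse - r.rmse,
        })
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Benchmark results as a table with unit-explicit columns."""
    return pd.DataFrame([{
        "method": r.method,
        "protocol": r.protocol,
        "mae_t_ha": r.mae,
        "mse_t_ha2": r.mse,
        "rmse_t_ha": r.rmse,
    } for r in results])
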