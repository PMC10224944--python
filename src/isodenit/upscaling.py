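"""Random-forest upscaling of grid-cell soil delta15N to a global surface.

A random forest is trained on cell-mean d15N against 16 gridded
environmental predictors (climate, soil properties, microbial symbionts,
GPP, N deposition), evaluated by a seeded hold-out split and K-fold CV,
and compared with a climate-only (T, P) ordinary-least-squares baseline —
the linear-upscaling approach the forest replaces.  Prediction uncertainty
is the spread across trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

PREDICTORS = [
    "P", "T", "P_PET", "BD", "pH", "clay", "silt", "sand",
    "OC", "CN", "AM", "ECM", "Nfix", "GPP", "NHx", "NOy",
]

MIN_ROWS = 30
TARGET = "delta15n"


def build_feature_table(
    cells: pd.DataFrame, predictors: Mapping[str, xr.DataArray]
) -> pd.DataFrame:
    """Join gridded predictors onto aggregated observation cells.

    ``cells`` is the output of :func:`isodenit.sites.aggregate_to_grid`
    (one row per occupied cell with ``ilat``/``ilon`` and the cell-mean
    d15N).  Rows where any predictor is masked are dropped.
    """
    table = cells.copy()
    ilat = cells["ilat"].to_numpy(int)
    ilon = cells["ilon"].to_numpy(int)
    for name, field in predictors.items():
        table[name] = np.asarray(field.values, float)[ilat, ilon]
    return table.dropna(subset=list(predictors)).reset_index(drop=True)


@dataclass(frozen=True)
class FitStats:
    """Goodness of fit on one evaluation set: R^2 = 1 - SSE/SST, RMSE (permil)."""

    r2: float
    rmse: float
    n: int


def _stats(y: np.ndarray, yhat: np.ndarray) -> FitStats:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return FitStats(r2=r2, rmse=float(np.sqrt(sse / len(y))), n=len(y))


def _check_table(
    table: pd.DataFrame, predictors: Sequence[str], min_rows: int = MIN_ROWS
) -> None:
    missing = [c for c in [*predictors, TARGET] if c not in table.columns]
    if missing:
        raise KeyError(f"feature table is missing columns: {missing}")
    if len(table) < min_rows:
        raise ValueError(f"need at least {min_rows} rows to fit, got {len(table)}")
    if table[list(predictors)].isna().any().any():
        raise ValueError("feature table has missing predictor values")


def train_test_split_table(
    table: pd.DataFrame, test_frac: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded row split (default 80/20 train/test)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(table))
    n_test = int(round(test_frac * len(table)))
    return table.iloc[idx[n_test:]], table.iloc[idx[:n_test]]


def fit_delta15n_model(
    table: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    predictors: Sequence[str] = PREDICTORS,
) -> tuple[RandomForestRegressor, FitStats]:
    """Fit the random forest and report training-set statistics.

    Defaults: 500 trees, unlimited depth, sqrt(features) per split.
    """
    _check_table(table, predictors)
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed),
        n_jobs=1,
    )
    X = table[list(predictors)].to_numpy(float)
    y = table[TARGET].to_numpy(float)
    model.fit(X, y)
    model.predictor_names_ = list(predictors)
    return model, _stats(y, model.predict(X))


def evaluate(
    model: RandomForestRegressor, table: pd.DataFrame
) -> FitStats:
    X = table[list(model.predictor_names_)].to_numpy(float)
    return _stats(table[TARGET].to_numpy(float), model.predict(X))


def kfold_cv(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    predictors: Sequence[str] = PREDICTORS,
) -> list[FitStats]:
    """K-fold cross-validation: each fold scored by a forest fit on the rest.

    Folds come from a seeded shuffle of row positions, so the result does
    not depend on input row order.
    """
    if not 2 <= k <= len(table):
        raise ValueError(f"k must be in [2, {len(table)}], got {k}")
    _check_table(table, predictors)
    table = table.sort_index()
    out = []
    for train_ix, test_ix in KFold(n_splits=k, shuffle=True, random_state=seed).split(
        table
    ):
        model, _ = fit_delta15n_model(
            table.iloc[train_ix], n_trees=n_trees, seed=seed, predictors=predictors
        )
        out.append(evaluate(model, table.iloc[test_ix]))
    return out


def predict_grid(
    model: RandomForestRegressor, predictors: Mapping[str, xr.DataArray]
) -> tuple[xr.DataArray, xr.DataArray]:
    """Predict the d15N surface and its across-tree SD from predictor rasters.

    Output is masked wherever any predictor is masked.
    """
    names = list(model.predictor_names_)
    missing = [n for n in names if n not in predictors]
    if missing:
        raise KeyError(f"missing predictor layers: {missing}")
    ref = predictors[names[0]]
    stack = np.stack([np.asarray(predictors[n].values, float) for n in names], axis=-1)
    valid = np.all(np.isfinite(stack), axis=-1)
    X = stack[valid]
    pred = np.full(ref.shape, np.nan)
    sd = np.full(ref.shape, np.nan)
    if X.size:
        per_tree = np.stack([t.predict(X) for t in model.estimators_])
        pred[valid] = per_tree.mean(axis=0)
        sd[valid] = per_tree.std(axis=0)
    return (
        ref.copy(data=pred).rename("delta15n"),
        ref.copy(data=sd).rename("delta15n_sd"),
    )


def fit_linear_baseline(
    table: pd.DataFrame, predictors: Sequence[str] = ("T", "P")
) -> tuple[dict[str, float], FitStats]:
    """Climate-only OLS baseline: d15N ~ T + P + intercept."""
    import statsmodels.api as sm

    _check_table(table, predictors, min_rows=len(predictors) + 2)
    X = sm.add_constant(table[list(predictors)].to_numpy(float))
    y = table[TARGET].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    coeffs = {"const": float(fit.params[0])}
    coeffs.update({p: float(c) for p, c in zip(predictors, fit.params[1:])})
    return coeffs, _stats(y, fit.fittedvalues)


def predict_linear(
    coeffs: Mapping[str, float], table: pd.DataFrame
) -> np.ndarray:
    names = [k for k in coeffs if k != "const"]
    return coeffs["const"] + sum(
        coeffs[n] * table[n].to_numpy(float) for n in names
    )


def feature_importance(
    model: RandomForestRegressor,
    table: pd.DataFrame,
    seed: int = 0,
    n_repeats: int = 10,
) -> list[tuple[str, float]]:
    """Permutation importance on held-out rows, ranked descending.

    Permutation (rather than impurity) importance is comparable across
    feature scales and measures loss of predictive skill directly.
    """
    names = list(model.predictor_names_)
    X = table[names].to_numpy(float)
    y = table[TARGET].to_numpy(float)
    res = permutation_importance(
        model, X, y, n_repeats=n_repeats, random_state=int(seed)
    )
    order = np.argsort(res.importances_mean)[::-1]
    return [(names[i], float(res.importances_mean[i])) for i in order]
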