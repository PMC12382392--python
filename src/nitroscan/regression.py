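"""Trait regression: SVR, random forest, and Lasso over feature tables.

A feature table is a pandas DataFrame with one row per plant, the spectral
and/or structural feature columns, and the measured trait columns (TRN, NO3,
DW). Models are fit on a reproducible 70/30 train/test split (stratified by
dose group when group sizes permit) and evaluated with the five-metric suite
ME, MAE, RMSE, rRMSE and R². Feature relevance is the mean absolute
linear-SVR coefficient per standardized feature, normalized to sum to one,
averaged over repeated random splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .spectral import INDEX_NAMES
from .structural import FEATURE_NAMES as STRUCTURAL_NAMES

__all__ = [
    "SPECTRAL_FEATURES", "STRUCTURAL_FEATURES", "TRAIT_NAMES",
    "ModelConfig", "EvalMetrics", "feature_columns",
    "split_table", "compute_metrics", "fit_predict", "relevance",
]

SPECTRAL_FEATURES: tuple[str, ...] = tuple(INDEX_NAMES)
STRUCTURAL_FEATURES: tuple[str, ...] = tuple(STRUCTURAL_NAMES)
TRAIT_NAMES = ("TRN", "NO3", "DW")

_DEFAULT_GRIDS = {
    "SVR": {"C": [0.1, 1, 10, 100], "epsilon": [0.01, 0.1, 1]},
    "RF": {"n_estimators": [50, 100, 200], "max_depth": [3, 5, 8]},
    "Lasso": {"alpha": [0.001, 0.01, 0.1]},
}


@dataclass(frozen=True)
class ModelConfig:
    """Model choice and hyperparameters (defaults: the study's reported optima)."""

    model: str = "RF"            # SVR | RF | Lasso
    svr_c: float = 10.0
    svr_epsilon: float = 0.1
    svr_kernel: str = "linear"
    rf_trees: int = 100
    rf_max_depth: int = 5
    lasso_alpha: float = 0.01
    grid_search: bool = False
    cv_folds: int = 5
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("SVR", "RF", "Lasso"):
            raise ValueError("model must be one of SVR, RF, Lasso")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split fraction must be in (0, 1)")


@dataclass(frozen=True)
class EvalMetrics:
    """ME/MAE/RMSE in trait units; rRMSE and R² unitless.

    rRMSE divides RMSE by the mean observed test value and is NaN when that
    mean is zero.
    """

    me: float
    mae: float
    rmse: float
    rrmse: float
    r2: float

    def as_dict(self) -> dict[str, float]:
        return {"ME": self.me, "MAE": self.mae, "RMSE": self.rmse,
                "rRMSE": self.rrmse, "R2": self.r2}


class PredictionResult(NamedTuple):
    predictions: np.ndarray
    metrics: EvalMetrics
    model: object


def feature_columns(feature_set: str) -> tuple[str, ...]:
    """Column names for a feature-set tag: spectral, structural, or combined."""
    if feature_set == "spectral":
        return SPECTRAL_FEATURES
    if feature_set == "structural":
        return STRUCTURAL_FEATURES
    if feature_set == "combined":
        return SPECTRAL_FEATURES + STRUCTURAL_FEATURES
    raise ValueError(f"unknown feature set {feature_set!r}")


def split_table(
    table: pd.DataFrame,
    fraction: float = 0.7,
    seed: int = 0,
    stratify_by: str | None = "dose_ppm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible train/test split, stratified by dose group when possible.

    The test partition is floored: test = floor(n·(1−fraction)), so 84 rows at
    fraction 0.7 give 59 train / 25 test. Falls back to an unstratified split
    when any group has < 2 members or the test set is smaller than the number
    of groups.
    """
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_test = int(np.floor(n * (1.0 - fraction)))
    if n_test == 0 or n_test == n:
        raise ValueError("split fraction leaves an empty partition")

    strat = None
    if stratify_by is not None and stratify_by in table.columns:
        groups = table[stratify_by]
        counts = groups.value_counts()
        if counts.min() >= 2 and n_test >= len(counts) and (n - n_test) >= len(counts):
            strat = groups
    train, test = train_test_split(
        table, test_size=n_test, random_state=seed, stratify=strat
    )
    return train, test


def compute_metrics(obs: np.ndarray, pred: np.ndarray) -> EvalMetrics:
    """ME, MAE, RMSE, rRMSE and R² of predictions against observations."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("obs and pred must be equal-length, nonempty")
    err = pred - obs
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mean_obs = float(np.mean(obs))
    rrmse = rmse / mean_obs if mean_obs != 0 else float("nan")
    ss_tot = float(np.sum((obs - mean_obs) ** 2))
    ss_res = float(np.sum(err**2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return EvalMetrics(me=me, mae=mae, rmse=rmse, rrmse=rrmse, r2=r2)


def _make_estimator(cfg: ModelConfig):
    if cfg.model == "SVR":
        return SVR(kernel=cfg.svr_kernel, C=cfg.svr_c, epsilon=cfg.svr_epsilon)
    if cfg.model == "RF":
        return RandomForestRegressor(
            n_estimators=cfg.rf_trees, max_depth=cfg.rf_max_depth,
            random_state=cfg.seed,
        )
    return Lasso(alpha=cfg.lasso_alpha, max_iter=100_000, tol=1e-3)


def fit_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    target: str,
    cfg: ModelConfig,
    features: tuple[str, ...] | None = None,
) -> PredictionResult:
    """Fit on the training rows, predict and score on the test rows.

    SVR and Lasso see z-scored features whose statistics come from the
    training split only; the random forest uses raw features. With
    ``cfg.grid_search`` the hyperparameters are tuned by k-fold
    cross-validation inside the training split.
    """
    if features is None:
        features = tuple(c for c in train.columns if c not in TRAIT_NAMES + ("plant_id", "dose_ppm"))
    missing = [c for c in features if c not in test.columns]
    if missing:
        raise ValueError(f"test table missing feature columns {missing}")
    y_train = train[target].to_numpy(dtype=float)
    y_test = test[target].to_numpy(dtype=float)
    if np.ptp(y_train) == 0:
        raise ValueError(f"zero-variance target {target!r} in training split")

    X_train = train[list(features)].to_numpy(dtype=float)
    X_test = test[list(features)].to_numpy(dtype=float)
    if cfg.model in ("SVR", "Lasso"):
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)

    est = _make_estimator(cfg)
    if cfg.grid_search:
        est = GridSearchCV(est, _DEFAULT_GRIDS[cfg.model], cv=cfg.cv_folds)
    est.fit(X_train, y_train)
    pred = est.predict(X_test)
    return PredictionResult(pred, compute_metrics(y_test, pred), est)


def relevance(
    table: pd.DataFrame,
    target: str,
    cfg: ModelConfig | None = None,
    iterations: int = 100,
    features: tuple[str, ...] | None = None,
) -> pd.Series:
    """Normalized linear-SVR feature weights averaged over random splits.

    Each iteration draws a fresh train/test split from the master seed, fits
    a linear-kernel SVR on z-scored features, takes |coefficient| per feature
    normalized to sum to one, and the weights are averaged across iterations
    (so they again sum to one). Only the linear kernel admits well-defined
    per-feature weights.
    """
    cfg = cfg or ModelConfig(model="SVR")
    if cfg.svr_kernel != "linear":
        raise ValueError("feature relevance requires a linear SVR kernel")
    if features is None:
        features = tuple(c for c in table.columns if c not in TRAIT_NAMES + ("plant_id", "dose_ppm"))
    seeds = np.random.SeedSequence(cfg.seed).generate_state(iterations) % (2**31)
    weights = np.zeros(len(features))
    for s in seeds:
        train, _ = split_table(table, cfg.split_fraction, seed=int(s))
        X = StandardScaler().fit_transform(train[list(features)].to_numpy(dtype=float))
        y = train[target].to_numpy(dtype=float)
        svr = SVR(kernel="linear", C=cfg.svr_c, epsilon=cfg.svr_epsilon).fit(X, y)
        w = np.abs(np.ravel(svr.coef_))
        total = w.sum()
        if total > 0:
            weights += w / total
    weights /= iterations
    result = pd.Series(weights, index=list(features), name=target)
    result.attrs["iterations"] = iterations
    return result
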