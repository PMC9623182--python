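"""Correlation screening, feature selection and PNC regression models.

The trial's fixed replication split is used throughout: replicates 1 and 3
calibrate (n = 32 at the default design), replicate 2 validates (n = 16).
Models are multiple linear regression (ordinary least squares with
intercept), k-nearest-neighbor regression on z-scored features (k = 5,
uniform weights, Euclidean distance) and a random forest (500 trees,
ceil(p/3) candidate features per split, bootstrap resampling, seeded).

Metrics: R^2 = 1 - SSE/SST, RMSE in %PNC units, and NRMSE = RMSE divided by
the mean of the observed values, in percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError
from .indices import INDEX_ORDER
from .synth import STAGES

__all__ = [
    "METHODS",
    "MP_COLUMNS",
    "EvalMetrics",
    "ModelReport",
    "pearson_screen",
    "select_top_vis",
    "split_by_replication",
    "fit_model",
    "regression_metrics",
    "evaluate",
    "summarize_ground_truth",
    "run_model_suite",
]

METHODS = ("MLR", "KNN", "RF")
MP_COLUMNS = {"H": "H_cm", "CC": "CC", "CV": "CV"}
_SINGLE_MPS = ("H", "CC", "CV")


# ---------------------------------------------------------------------------
# screening and selection
# ---------------------------------------------------------------------------


def pearson_screen(features: pd.DataFrame, pnc: pd.Series | np.ndarray, alpha: float = 0.01) -> pd.DataFrame:
    """Pearson correlation of every feature column with PNC.

    Two-sided p-values come from the t transform with n - 2 degrees of
    freedom; no multiple-testing correction is applied.  Zero-variance
    features get NaN and are flagged not significant (with a warning).
    Returns columns ``feature, r, p, significant``.
    """
    y = np.asarray(pnc, dtype=float)
    if len(features) != len(y):
        raise ValidationError("features and PNC must have equal length")
    if len(y) < 3:
        raise ValidationError("need at least 3 paired observations")
    rows = []
    for name in features.columns:
        x = np.asarray(features[name], dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"feature {name!r}: zero variance, correlation undefined")
            rows.append((name, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((name, float(r), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["feature", "r", "p", "significant"])


def select_top_vis(table: pd.DataFrame, k: int = 5) -> list[str]:
    """The k vegetation indices with the largest |r|.

    Only registry indices compete (morphological parameters are never
    selected here); ties break by registry order.
    """
    vis = table[table["feature"].isin(INDEX_ORDER)].copy()
    vis = vis[np.isfinite(vis["r"])]
    if len(vis) < k:
        raise ValidationError(f"need at least {k} finite VI correlations, have {len(vis)}")
    vis["abs_r"] = vis["r"].abs()
    vis["registry"] = vis["feature"].map({n: i for i, n in enumerate(INDEX_ORDER)})
    vis = vis.sort_values(["abs_r", "registry"], ascending=[False, True], kind="stable")
    return list(vis["feature"].head(k))


def split_by_replication(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed calibration/validation partition: reps {1, 3} train, rep 2 validates."""
    if "replication" not in table.columns:
        raise ValidationError("table must carry a 'replication' column")
    reps = table["replication"].astype(int)
    if not reps.isin((1, 2, 3)).all():
        raise ValidationError("replication labels must be in {1, 2, 3}")
    train = table[reps.isin((1, 3))]
    val = table[reps == 2]
    if len(train) == 0:
        raise ValidationError("empty training set: no plots in replications 1 or 3")
    if len(val) == 0:
        raise ValidationError("empty validation set: no plots in replication 2")
    return train, val


# ---------------------------------------------------------------------------
# model fitting and evaluation
# ---------------------------------------------------------------------------


def fit_model(method: str, X_train: np.ndarray, y_train: np.ndarray, hyper: dict | None = None, seed: int = 0):
    """Fit one of the three regressors; returns an object with ``predict``."""
    hyper = hyper or {}
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X_train must be 2-D")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed in model inputs")
    n, p = X.shape
    if method == "MLR":
        if n <= p:
            raise ValidationError(f"MLR needs n_train > n_features, got n={n}, p={p}")
        design = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(design) < p + 1:
            raise ValidationError("singular design matrix")
        return LinearRegression().fit(X, y)
    if method == "KNN":
        k = int(hyper.get("k", 5))
        if k > n:
            raise ValidationError(f"KNN needs k <= n_train, got k={k}, n={n}")
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("knn", KNeighborsRegressor(n_neighbors=k, weights="uniform", metric="euclidean")),
            ]
        ).fit(X, y)
    if method == "RF":
        n_trees = int(hyper.get("n_trees", 500))
        return RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max(1, math.ceil(p / 3)),
            bootstrap=True,
            random_state=seed,
        ).fit(X, y)
    raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")


@dataclass
class EvalMetrics:
    """R^2, RMSE (%PNC units) and NRMSE (% of the observed mean)."""

    r2: float
    rmse: float
    nrmse: float

    def to_dict(self) -> dict:
        return {"R2": self.r2, "RMSE": self.rmse, "NRMSE": self.nrmse}


def regression_metrics(y_obs: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    """R^2 = 1 - SSE/SST; RMSE = sqrt(SSE/n); NRMSE = RMSE / mean(y_obs) * 100."""
    y = np.asarray(y_obs, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValidationError("need >= 2 paired observations of equal length")
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        warnings.warn("zero variance in observations: R^2 undefined")
        r2 = np.nan
    else:
        r2 = 1.0 - sse / sst
    rmse = math.sqrt(sse / y.size)
    nrmse = rmse / y.mean() * 100.0 if y.mean() != 0 else np.nan
    return EvalMetrics(r2=r2, rmse=rmse, nrmse=nrmse)


def evaluate(model, X: np.ndarray, y_obs: np.ndarray) -> EvalMetrics:
    """Predict with a fitted model and score against observations."""
    return regression_metrics(np.asarray(y_obs, dtype=float), model.predict(np.asarray(X, dtype=float)))


def summarize_ground_truth(values: np.ndarray) -> dict:
    """Max, min, mean, sample SD (n-1) and coefficient of variation in %."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values to summarize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = sd / mean * 100.0 if mean != 0 else np.nan
    if mean == 0:
        warnings.warn("zero mean: CV% undefined")
    return {"max": float(v.max()), "min": float(v.min()), "mean": mean, "sd": sd, "cv_pct": cv}


# ---------------------------------------------------------------------------
# the full suite
# ---------------------------------------------------------------------------


@dataclass
class ModelReport:
    """One method x stage x feature-set result with both partitions."""

    method: str
    stage: str
    feature_set: str
    features: list[str]
    n_train: int
    n_val: int
    calibration: EvalMetrics
    validation: EvalMetrics

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "stage": self.stage,
            "feature_set": self.feature_set,
            "features": self.features,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "calibration": self.calibration.to_dict(),
            "validation": self.validation.to_dict(),
        }


def _resolve_features(feature_set: str, screen: pd.DataFrame, top_k: int) -> list[str]:
    if feature_set == "VIs":
        return select_top_vis(screen, k=top_k)
    if feature_set == "MPs":
        return list(MP_COLUMNS.values())
    if feature_set == "VIs+MPs":
        return select_top_vis(screen, k=top_k) + list(MP_COLUMNS.values())
    if feature_set in _SINGLE_MPS:
        return [MP_COLUMNS[feature_set]]
    raise ValidationError(f"unknown feature set {feature_set!r}")


def run_model_suite(
    features: pd.DataFrame,
    truth: pd.DataFrame,
    stages: tuple[str, ...] = STAGES,
    methods: tuple[str, ...] = METHODS,
    feature_sets: tuple[str, ...] = ("VIs", "MPs", "VIs+MPs"),
    seed: int = 0,
    top_k: int = 5,
    hyper: dict | None = None,
) -> list[ModelReport]:
    """Fit and score every stage x method x feature-set combination.

    ``features`` carries per plot x stage VI means and morphological
    parameters; ``truth`` carries ``plot_id, stage (optional), replication,
    pnc``.  Candidate indices for the "VIs" sets are ranked by their
    training-partition correlation with PNC (the validation fold never
    informs selection).
    """
    join_cols = ["plot_id", "stage"] if "stage" in truth.columns else ["plot_id"]
    merged = features.merge(truth, on=join_cols, how="left", suffixes=("", "_truth"))
    if merged["pnc"].isna().any():
        missing = merged.loc[merged["pnc"].isna(), "plot_id"].tolist()
        raise ValidationError(f"join failure: no PNC for plots {missing}")

    reports: list[ModelReport] = []
    for stage in stages:
        sub = merged[merged["stage"] == stage]
        if sub.empty:
            raise ValidationError(f"no rows for stage {stage!r}")
        train, val = split_by_replication(sub)
        vi_cols = [c for c in INDEX_ORDER if c in sub.columns]
        screen = pearson_screen(train[vi_cols], train["pnc"])
        for feature_set in feature_sets:
            cols = _resolve_features(feature_set, screen, top_k)
            for method in methods:
                model = fit_model(
                    method,
                    train[cols].to_numpy(float),
                    train["pnc"].to_numpy(float),
                    hyper=hyper,
                    seed=seed,
                )
                reports.append(
                    ModelReport(
                        method=method,
                        stage=stage,
                        feature_set=feature_set,
                        features=cols,
                        n_train=len(train),
                        n_val=len(val),
                        calibration=evaluate(model, train[cols].to_numpy(float), train["pnc"].to_numpy(float)),
                        validation=evaluate(model, val[cols].to_numpy(float), val["pnc"].to_numpy(float)),
                    )
                )
    return reports
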