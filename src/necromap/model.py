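"""Feature screening and validation harness for the MNC regressor.

Candidate predictors (environmental variables plus eco-cluster relative
abundances) are ranked by random-forest permutation importance and the top
fraction (default 70%) retained. Two feature sets are assembled from the
selection: CE ("contains eco-clusters") keeps everything, WE ("without
eco-clusters") drops the cluster-abundance variables. Model skill is
reported as the metric suite used for observed-vs-predicted evaluation:
OLS slope of observed on predicted, Pearson's r, R-squared, RMSE, MSE and
MAE, pooled over ten-fold cross-validation and on a 25% stratified hold-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .sae import SaeConfig, SaeRegressor

__all__ = [
    "FeatureSpec",
    "ValidationReport",
    "regression_metrics",
    "rank_variable_importance",
    "select_top_fraction",
    "kfold_validate",
    "holdout_validate",
    "sae_factory",
]


def regression_metrics(obs, pred) -> dict[str, float]:
    """Metric suite on observed vs predicted values.

    slope is the OLS slope of obs regressed on pred (0 when pred is
    constant); R2 = 1 - SSres/SStot with residuals obs - pred; RMSE is the
    square root of MSE. Raises on constant observations, for which R2 is
    undefined.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if len(obs) != len(pred) or len(obs) < 2:
        raise ValueError("obs and pred must have equal length >= 2")
    if np.ptp(obs) == 0:
        raise ValueError("constant observations: metrics undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    var_pred = float(np.var(pred))
    slope = float(np.cov(pred, obs, bias=True)[0, 1] / var_pred) if var_pred > 0 else 0.0
    r = float(stats.pearsonr(obs, pred).statistic) if var_pred > 0 else float("nan")
    mse = ss_res / len(obs)
    return {
        "slope": slope,
        "pearson_r": r,
        "R2": 1.0 - ss_res / ss_tot,
        "RMSE": math.sqrt(mse),
        "MSE": mse,
        "MAE": float(np.mean(np.abs(obs - pred))),
    }


@dataclass
class FeatureSpec:
    """Importance-ranked candidates and the derived CE/WE feature sets."""

    ranked: pd.DataFrame           # variable, importance (descending)
    selected: list[str]
    ce_set: list[str]
    we_set: list[str]
    fraction: float = 0.70


def rank_variable_importance(
    X: pd.DataFrame,
    y,
    seed: int = 0,
    n_trees: int = 500,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Permutation-importance ranking from an RF regression of MNC on all
    candidate variables; deterministic given the seed. Requires n >= 30."""
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 30:
        raise ValueError(f"need n >= 30 for importance ranking, got {len(y)}")
    if np.ptp(y) == 0:
        raise ValueError("constant target: importance undefined")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(dtype=float), y)
    pi = permutation_importance(
        rf, X.to_numpy(dtype=float), y, n_repeats=n_repeats, random_state=seed
    )
    out = pd.DataFrame(
        {"variable": list(X.columns), "importance": pi.importances_mean}
    ).sort_values(
        ["importance", "variable"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def select_top_fraction(
    ranked: pd.DataFrame,
    fraction: float = 0.70,
    cluster_vars: set[str] | None = None,
) -> FeatureSpec:
    """Keep the top ceil(fraction * n) ranked variables; the CE set is the
    selection, the WE set is the selection minus eco-cluster variables."""
    if len(ranked) == 0:
        raise ValueError("empty ranking")
    cluster_vars = cluster_vars or set()
    n_sel = math.ceil(fraction * len(ranked))
    selected = ranked["variable"].tolist()[:n_sel]
    ce = list(selected)
    we = [v for v in selected if v not in cluster_vars]
    return FeatureSpec(ranked=ranked, selected=selected, ce_set=ce, we_set=we,
                       fraction=fraction)


@dataclass
class ValidationReport:
    """Per-fold and pooled observed-vs-predicted metrics."""

    pooled: dict[str, float]
    per_fold: pd.DataFrame | None = None
    fold_assignments: np.ndarray | None = None   # fold index per sample
    holdout_indices: np.ndarray | None = None
    predictions: pd.DataFrame | None = None      # obs, pred (+ index)


def sae_factory(config: SaeConfig | None = None):
    """Model factory: input_dim -> untrained :class:`SaeRegressor`."""
    def make(input_dim: int, seed: int) -> SaeRegressor:
        base = config or SaeConfig()
        cfg = SaeConfig(**{**base.__dict__, "seed": seed})
        return SaeRegressor(input_dim, cfg)
    return make


def _fit_predict(factory, X_tr, y_tr, X_te, seed):
    model = factory(X_tr.shape[1], seed)
    model.fit(X_tr, y_tr)
    return model.predict(X_te)


def kfold_validate(
    X: pd.DataFrame,
    y,
    k: int = 10,
    seed: int = 0,
    model_factory=None,
) -> ValidationReport:
    """k-fold cross-validation with balanced folds (sizes differ by <= 1).

    The model is retrained per fold and metrics are pooled over the
    out-of-fold predictions.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    factory = model_factory or sae_factory()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    assign = np.empty(n, dtype=int)
    oof = np.empty(n)
    rows = []
    Xv = X.to_numpy(dtype=float)
    for i, te in enumerate(folds):
        assign[te] = i
        tr = np.setdiff1d(perm, te)
        pred = _fit_predict(
            factory,
            pd.DataFrame(Xv[tr], columns=X.columns), y[tr],
            pd.DataFrame(Xv[te], columns=X.columns), seed + i,
        )
        oof[te] = np.asarray(pred)
        if len(te) >= 2 and np.ptp(y[te]) > 0:
            rows.append({"fold": i, **regression_metrics(y[te], oof[te])})
    pooled = regression_metrics(y, oof)
    return ValidationReport(
        pooled=pooled,
        per_fold=pd.DataFrame(rows),
        fold_assignments=assign,
        predictions=pd.DataFrame({"obs": y, "pred": oof}, index=X.index),
    )


def holdout_validate(
    X: pd.DataFrame,
    y,
    classes=None,
    holdout_frac: float = 0.25,
    seed: int = 0,
    model_factory=None,
) -> ValidationReport:
    """Hold-out validation: train on (1 - holdout_frac) of the sites,
    evaluate on the rest, split stratified by grassland class when given.
    Requires n >= 20."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 20:
        raise ValueError(f"need n >= 20 for hold-out validation, got {n}")
    factory = model_factory or sae_factory()
    idx = np.arange(n)
    tr, te = train_test_split(
        idx,
        test_size=holdout_frac,
        random_state=seed,
        shuffle=True,
        stratify=None if classes is None else np.asarray(classes),
    )
    Xv = X.to_numpy(dtype=float)
    pred = np.asarray(_fit_predict(
        factory,
        pd.DataFrame(Xv[tr], columns=X.columns), y[tr],
        pd.DataFrame(Xv[te], columns=X.columns), seed,
    ))
    pooled = regression_metrics(y[te], pred)
    return ValidationReport(
        pooled=pooled,
        holdout_indices=te,
        predictions=pd.DataFrame({"obs": y[te], "pred": pred}, index=te),
    )
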