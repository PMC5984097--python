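"""Model evaluation: accuracy metrics, cross-validation, permutation test,
brain-PAD computation, and the volumetric baseline age model."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import KFold, StratifiedKFold

from .gpr import SimilarityGPRegressor

__all__ = [
    "PredictionMetrics", "prediction_metrics", "kfold_cv", "permutation_pvalue",
    "BrainPADTable", "brain_pad", "VolumetricAgeModel", "volumetric_age_model",
]


@dataclass
class PredictionMetrics:
    """Agreement between predicted and chronological age.

    ``r_squared`` is the squared Pearson correlation (so an r of 0.94
    corresponds to 88% of variance explained); ``mae <= rmse`` always.
    """

    pearson_r: float
    r_squared: float
    mae: float
    rmse: float
    n: int
    permutation_p: float | None = None
    n_permutations: int | None = None


def prediction_metrics(y_true, y_pred) -> PredictionMetrics:
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    err = y_pred - y_true
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(y_true, y_pred).statistic)
    return PredictionMetrics(
        pearson_r=r,
        r_squared=r**2 if np.isfinite(r) else np.nan,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        n=len(y_true),
    )


def _age_folds(y, k, seed, stratify):
    """Seeded k-fold partition, stratified by age decile when feasible."""
    n = len(y)
    if stratify:
        n_bins = min(10, max(2, n // (2 * k)))
        labels = pd.qcut(pd.Series(y).rank(method="first"), q=n_bins,
                         labels=False, duplicates="drop").to_numpy()
        if np.bincount(labels).min() >= k:
            return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed
                                   ).split(np.zeros(n), labels)
    return KFold(n_splits=k, shuffle=True, random_state=seed).split(np.zeros(n))


def kfold_cv(X, y, k: int = 10, seed: int = 0, estimator=None,
             stratify_by_age: bool = True, return_details: bool = False):
    """Pooled k-fold cross-validation of the age model.

    Each fold is predicted by an estimator fitted on the remaining folds
    (hyperparameters re-optimized per fold); metrics are computed on the
    pooled held-out predictions. Returns ``PredictionMetrics``, or a
    ``(metrics, details)`` pair with per-subject fold assignments and
    predictions when ``return_details`` is set.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} subjects")
    if estimator is None:
        estimator = SimilarityGPRegressor()
    pred = np.full(n, np.nan)
    fold_id = np.full(n, -1)
    for f, (train_idx, test_idx) in enumerate(_age_folds(y, k, seed, stratify_by_age)):
        model = clone(estimator).fit(X[train_idx], y[train_idx])
        pred[test_idx] = model.predict(X[test_idx])
        fold_id[test_idx] = f
    metrics = prediction_metrics(y, pred)
    if return_details:
        details = pd.DataFrame({"fold": fold_id, "age": y, "predicted_age": pred})
        return metrics, details
    return metrics


def permutation_pvalue(X, y, n_perm: int = 1000, seed: int = 0,
                       metric_fn=None, k: int = 10) -> tuple[float, float]:
    """Permutation-corrected p-value for the age-prediction accuracy.

    Re-shuffles the age labels ``n_perm`` times, recomputes the metric
    (default: pooled k-fold CV Pearson r) and reports
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)``.
    Returns ``(observed_metric, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, float).ravel()
    if metric_fn is None:
        def metric_fn(Xm, ym, _seed=seed, _k=k):
            return kfold_cv(Xm, ym, k=_k, seed=_seed).pearson_r
    observed = metric_fn(X, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = metric_fn(X, rng.permutation(y))
        if perm >= observed:
            exceed += 1
    return float(observed), (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# brain-PAD
# ---------------------------------------------------------------------------

@dataclass
class BrainPADTable:
    """Per-subject brain-PAD values plus sex-wise summary statistics."""

    table: pd.DataFrame
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def brain_pad(predicted, chronological, sex=None, dnam_age=None) -> BrainPADTable:
    """Brain-predicted age difference: predicted minus chronological age."""
    predicted = np.asarray(predicted, float).ravel()
    chronological = np.asarray(chronological, float).ravel()
    if predicted.shape != chronological.shape:
        raise ValueError("predicted and chronological ages must align")
    if np.isnan(predicted).any() or np.isnan(chronological).any():
        raise ValueError("NaN ages are not allowed")
    table = pd.DataFrame({
        "chronological_age": chronological,
        "predicted_age": predicted,
        "brain_pad": predicted - chronological,
    })
    if dnam_age is not None:
        dnam_age = np.asarray(dnam_age, float).ravel()
        table["dnam_age"] = dnam_age
        table["dnam_pad"] = dnam_age - chronological
    groups = {"all": table}
    if sex is not None:
        table["sex"] = np.asarray(sex)
        for label, sub in table.groupby("sex", sort=True):
            groups[str(label)] = sub
    rows = [
        {"group": label, "n": len(sub),
         "mean_brain_pad": sub["brain_pad"].mean(),
         "sd_brain_pad": sub["brain_pad"].std(ddof=1)}
        for label, sub in groups.items()
    ]
    return BrainPADTable(table=table, summary=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# volumetric baseline
# ---------------------------------------------------------------------------

class VolumetricAgeModel(RegressorMixin, BaseEstimator):
    """OLS of chronological age on GM, WM and CSF volume (ml)."""

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be subjects x volumes")
        if len(y) <= X.shape[1] + 1:
            raise ValueError("need n > number of volumes + 1")
        design = np.column_stack([np.ones(len(y)), X])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            warnings.warn("volume design matrix is rank deficient", RuntimeWarning)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        return self.intercept_ + X @ self.coef_


def volumetric_age_model(gm_vol, wm_vol, csf_vol, ages, cv: bool = False,
                         k: int = 10, seed: int = 0):
    """Fit the three-volume linear age model; returns (model, metrics).

    Metrics use the same definitions as :func:`kfold_cv`, either in-sample
    (default) or from pooled k-fold cross-validation.
    """
    X = np.column_stack([np.asarray(gm_vol, float), np.asarray(wm_vol, float),
                         np.asarray(csf_vol, float)])
    ages = np.asarray(ages, float).ravel()
    model = VolumetricAgeModel().fit(X, ages)
    if cv:
        metrics = kfold_cv(X, ages, k=k, seed=seed, estimator=VolumetricAgeModel())
    else:
        metrics = prediction_metrics(ages, model.predict(X))
    return model, metrics
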