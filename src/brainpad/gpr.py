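"""Gaussian-process age regression on the dot-product similarity matrix.

The model places a GP prior over age with covariance
``sigma_f^2 * K + sigma_n^2 * I`` where ``K`` is the (optionally
dimension-scaled) Gram matrix of the concatenated voxel features and ages are
mean-centred. With this linear kernel the predictive mean coincides with
dual-form ridge regression at ``lambda = sigma_n^2 / sigma_f^2``, so the
model operates in subject space (n x n) even when the voxel dimension is
large. Hyperparameters maximize the log marginal likelihood; a single
eigendecomposition of ``K`` makes every likelihood evaluation O(n).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kernel import similarity_matrix

__all__ = ["SimilarityGPRegressor", "NumericalError", "gpr_fit", "gpr_predict",
           "save_model", "load_model"]


class NumericalError(RuntimeError):
    """Raised when the kernel is non-PSD beyond tolerance or the optimizer fails."""


class SimilarityGPRegressor(RegressorMixin, BaseEstimator):
    """GP regression of age on a linear (dot-product) similarity kernel.

    Parameters
    ----------
    kernel : {"linear", "precomputed"}
        ``"linear"`` builds the Gram matrix from a subjects-by-voxels feature
        matrix; ``"precomputed"`` takes the square similarity matrix directly
        at fit time and a rectangular test-by-train matrix at predict time.
    scale_by_dim : bool
        Divide dot products by the feature count (ignored for precomputed).
    center_features : bool
        Subtract training-set voxel means before forming dot products
        (ignored for precomputed). Keeps the kernel signal-dominated when
        maps share a large common template.
    signal_variance, noise_variance : float or None
        Fix either hyperparameter; when both are given no marginal-likelihood
        optimization is performed.
    noise_floor : float
        Lower bound on ``sigma_n^2`` relative to ``var(y)``.

    Attributes
    ----------
    signal_variance_, noise_variance_ : optimized (or fixed) hyperparameters.
    dual_coef_ : ndarray, solution of ``(sf^2 K + sn^2 I) alpha = y - ybar``.
    y_train_mean_ : the age offset ``ybar``.
    log_marginal_likelihood_ : value at the optimum.
    """

    def __init__(self, kernel="linear", scale_by_dim=True, center_features=True,
                 signal_variance=None, noise_variance=None, noise_floor=1e-8,
                 max_restarts=None):
        self.kernel = kernel
        self.scale_by_dim = scale_by_dim
        self.center_features = center_features
        self.signal_variance = signal_variance
        self.noise_variance = noise_variance
        self.noise_floor = noise_floor
        self.max_restarts = max_restarts

    # -- internals ---------------------------------------------------------
    def _training_kernel(self, X):
        if self.kernel == "precomputed":
            K = np.asarray(X, float)
            if K.ndim != 2 or K.shape[0] != K.shape[1]:
                raise ValueError("precomputed kernel must be a square matrix")
            return K
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        self.feature_means_ = X.mean(axis=0) if self.center_features else np.zeros(X.shape[1])
        self.X_fit_ = X - self.feature_means_
        self.n_features_in_ = X.shape[1]
        return similarity_matrix(self.X_fit_, scale_by_dim=self.scale_by_dim)

    @staticmethod
    def _lml_terms(theta, lam, y2):
        sf2, sn2 = np.exp(theta)
        v = sf2 * lam + sn2
        lml = -0.5 * np.sum(y2 / v) - 0.5 * np.sum(np.log(v)) - 0.5 * len(lam) * np.log(2 * np.pi)
        # gradients wrt log sf2, log sn2
        common = 0.5 * (y2 / v**2 - 1.0 / v)
        grad = np.array([sf2 * np.sum(common * lam), sn2 * np.sum(common)])
        return lml, grad

    def fit(self, X, y):
        y = np.asarray(y, float).ravel()
        K = self._training_kernel(X)
        n = K.shape[0]
        if len(y) != n:
            raise ValueError(f"{len(y)} ages for {n} subjects")
        if n < 10:
            raise ValueError("need at least 10 training subjects")

        self.y_train_mean_ = float(y.mean())
        yc = y - self.y_train_mean_
        var_y = float(yc.var())

        K = 0.5 * (K + K.T)
        lam, V = np.linalg.eigh(K)
        trace = max(float(np.trace(K)), 0.0)
        # jitter-retry policy: negative modes within 1e-6 * trace / n are
        # attributed to round-off and clipped; anything larger is a real
        # PSD violation.
        allowed = 1e-6 * trace / max(n, 1) + 1e-12
        if lam.min() < -allowed:
            raise NumericalError(
                f"kernel is not PSD: min eigenvalue {lam.min():.3e} "
                f"(tolerance {-allowed:.3e})"
            )
        lam = np.clip(lam, 0.0, None)
        yt = V.T @ yc
        y2 = yt**2

        if var_y == 0.0:
            # zero-variance target: posterior mean is the constant age
            self.signal_variance_ = 1e-12
            self.noise_variance_ = 1.0
            self.dual_coef_ = np.zeros(n)
            self.log_marginal_likelihood_ = float(
                self._lml_terms(np.log([self.signal_variance_, self.noise_variance_]), lam, y2)[0]
            )
            self._eig_ = (lam, V)
            return self

        if self.signal_variance is not None and self.noise_variance is not None:
            sf2, sn2 = float(self.signal_variance), float(self.noise_variance)
            self.log_marginal_likelihood_ = float(
                self._lml_terms(np.log([sf2, sn2]), lam, y2)[0]
            )
        else:
            mean_lam = max(float(lam.mean()), 1e-300)
            floor = np.log(self.noise_floor * var_y)
            bounds = [
                (np.log(var_y / mean_lam) - 25.0, np.log(var_y / mean_lam) + 25.0),
                (floor, np.log(var_y) + 10.0),
            ]
            # documented multi-start: sf2 matching var(y), sn2 in
            # {0.1, 1} * var(y)
            starts = [
                np.array([np.log(var_y / mean_lam), np.log(0.1 * var_y)]),
                np.array([np.log(var_y / mean_lam), np.log(var_y)]),
            ]
            if self.signal_variance is not None:
                bounds[0] = (np.log(self.signal_variance),) * 2
                starts = [np.array([np.log(self.signal_variance), s[1]]) for s in starts]
            if self.noise_variance is not None:
                bounds[1] = (np.log(self.noise_variance),) * 2
                starts = [np.array([s[0], np.log(self.noise_variance)]) for s in starts]
            best = None
            for x0 in starts[: self.max_restarts]:
                res = optimize.minimize(
                    lambda th: tuple(-t for t in self._lml_terms(th, lam, y2)),
                    x0=x0, jac=True, method="L-BFGS-B", bounds=bounds,
                )
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.all(np.isfinite(best.x)):
                raise NumericalError(f"hyperparameter optimization failed: {best}")
            sf2, sn2 = np.exp(best.x)
            self.log_marginal_likelihood_ = float(-best.fun)

        self.signal_variance_ = float(sf2)
        self.noise_variance_ = float(sn2)
        v = sf2 * lam + sn2
        self.dual_coef_ = V @ (yt / v)
        self._eig_ = (lam, V)
        return self

    def predict(self, X):
        check_is_fitted(self, "dual_coef_")
        if self.kernel == "precomputed":
            K_cross = np.atleast_2d(np.asarray(X, float))
        else:
            X = np.atleast_2d(np.asarray(X, float))
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"feature dimension mismatch: model was fitted with "
                    f"{self.n_features_in_} features, got {X.shape[1]}"
                )
            K_cross = similarity_matrix(X - self.feature_means_, self.X_fit_,
                                        scale_by_dim=self.scale_by_dim)
        if K_cross.shape[1] != len(self.dual_coef_):
            raise ValueError(
                f"cross-kernel has {K_cross.shape[1]} columns for "
                f"{len(self.dual_coef_)} training subjects"
            )
        return self.signal_variance_ * (K_cross @ self.dual_coef_) + self.y_train_mean_


# -- functional surface -------------------------------------------------------

def gpr_fit(K, ages, **kwargs) -> SimilarityGPRegressor:
    """Fit the GP age model on a precomputed similarity matrix."""
    return SimilarityGPRegressor(kernel="precomputed", **kwargs).fit(K, ages)


def gpr_predict(model: SimilarityGPRegressor, K_cross) -> np.ndarray:
    """Apply learned coefficients to a rectangular test-by-train kernel."""
    return model.predict(K_cross)


# -- persistence --------------------------------------------------------------

def save_model(model: SimilarityGPRegressor, prefix) -> None:
    """Persist hyperparameters as JSON + arrays as an ``.npz`` sidecar."""
    check_is_fitted(model, "dual_coef_")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "kernel": model.kernel,
        "scale_by_dim": model.scale_by_dim,
        "center_features": model.center_features,
        "signal_variance": model.signal_variance_,
        "noise_variance": model.noise_variance_,
        "y_train_mean": model.y_train_mean_,
        "log_marginal_likelihood": model.log_marginal_likelihood_,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    arrays = {"dual_coef": model.dual_coef_}
    if model.kernel != "precomputed":
        arrays["X_fit"] = model.X_fit_
        arrays["feature_means"] = model.feature_means_
    np.savez(prefix.with_suffix(".npz"), **arrays)


def load_model(prefix) -> SimilarityGPRegressor:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    arrays = np.load(prefix.with_suffix(".npz"))
    model = SimilarityGPRegressor(
        kernel=meta["kernel"], scale_by_dim=meta["scale_by_dim"],
        center_features=meta["center_features"],
    )
    model.signal_variance_ = meta["signal_variance"]
    model.noise_variance_ = meta["noise_variance"]
    model.y_train_mean_ = meta["y_train_mean"]
    model.log_marginal_likelihood_ = meta["log_marginal_likelihood"]
    model.dual_coef_ = arrays["dual_coef"]
    if "X_fit" in arrays:
        model.X_fit_ = arrays["X_fit"]
        model.feature_means_ = arrays["feature_means"]
        model.n_features_in_ = model.X_fit_.shape[1]
    return model
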