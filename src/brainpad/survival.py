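"""Survival analysis: Cox proportional hazards from the partial likelihood,
Kaplan-Meier curves with Greenwood variance, and AUC-based comparison of
nested biomarker models.

The Cox estimator maximizes the Efron-tied (or Breslow) log partial
likelihood by Newton-Raphson on internally standardized covariates, with
standard errors from the inverse observed information and a proportional-
hazards check based on the correlation of scaled Schoenfeld residuals with
event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxPHModel", "ConvergenceError", "cox_fit", "relative_risk_percent",
    "KMCurve", "kaplan_meier", "km_estimate", "tertile_groups",
    "binary_auc", "delong_test", "AUCComparison", "model_auc_compare",
]


class ConvergenceError(RuntimeError):
    """Raised on monotone likelihood (separation) or Newton failure."""


def _unpack_survival(y):
    """Accept (time, event) tuples, 2-column arrays, DataFrames or structured
    arrays and return float time / int event vectors."""
    if isinstance(y, tuple) and len(y) == 2:
        time, event = y
    elif isinstance(y, pd.DataFrame):
        time, event = y.iloc[:, 0], y.iloc[:, 1]
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = list(y.dtype.names)
        # accept either (time, event) or sksurv's (event, time) ordering
        if np.asarray(y[names[0]]).dtype == bool:
            event, time = y[names[0]], y[names[1]]
        else:
            time, event = y[names[0]], y[names[1]]
    else:
        arr = np.asarray(y, float)
        time, event = arr[:, 0], arr[:, 1]
    time = np.asarray(time, float).ravel()
    event = np.asarray(event).ravel().astype(int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


class CoxPHModel:
    """Cox proportional-hazards regression (Efron or Breslow ties).

    Fitted attributes: ``coef_`` (log hazard ratios), ``hazard_ratios_``,
    ``standard_errors_``, ``confidence_intervals_`` (on the HR scale),
    ``z_``, ``p_values_``, ``log_partial_likelihood_``, ``ph_test_``
    (per-covariate Schoenfeld p), ``converged_``, ``summary`` (DataFrame).
    """

    def __init__(self, ties: str = "efron", max_iter: int = 100,
                 tol: float = 1e-9, grad_tol: float = 1e-6, alpha: float = 0.05):
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self.max_iter = max_iter
        self.tol = tol
        self.grad_tol = grad_tol
        self.alpha = alpha

    # -- likelihood machinery ---------------------------------------------
    def _loglik(self, beta, X, time, event):
        """Efron/Breslow log partial likelihood, gradient and information.

        ``X`` must be sorted by ascending time.
        """
        n, p = X.shape
        eta = X @ beta
        eta -= eta.max()  # guard overflow; partial likelihood is invariant
        # extreme trial points in the line search may under/overflow; the
        # resulting non-finite likelihood is rejected by the caller
        err = np.errstate(over="ignore", under="ignore",
                          invalid="ignore", divide="ignore")
        err.__enter__()
        w = np.exp(eta)
        # suffix sums over the risk set (time_i >= t)
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1],
                       axis=0)[::-1]
        ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j < n and time[j] == time[i]:
                j += 1
            dead = np.arange(i, j)[event[i:j] == 1]
            d = len(dead)
            if d:
                s0r, s1r, s2r = S0[i], S1[i], S2[i]
                ll += eta[dead].sum()
                grad += X[dead].sum(axis=0)
                if self.ties == "efron" and d > 1:
                    wd = w[dead]
                    s0d = wd.sum()
                    s1d = (wd[:, None] * X[dead]).sum(axis=0)
                    s2d = (wd[:, None, None]
                           * (X[dead][:, :, None] * X[dead][:, None, :])).sum(axis=0)
                    for ell in range(d):
                        f = ell / d
                        phi0 = s0r - f * s0d
                        phi1 = s1r - f * s1d
                        phi2 = s2r - f * s2d
                        ll -= np.log(phi0)
                        mu = phi1 / phi0
                        grad -= mu
                        info += phi2 / phi0 - np.outer(mu, mu)
                else:
                    ll -= d * np.log(s0r)
                    mu = s1r / s0r
                    grad -= d * mu
                    info += d * (s2r / s0r - np.outer(mu, mu))
            i = j
        err.__exit__(None, None, None)
        return ll, grad, info

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.covariate_names_ = list(X.columns)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
            if X.ndim == 1:
                X = X[:, None]
            self.covariate_names_ = [f"x{i}" for i in range(X.shape[1])]
        time, event = _unpack_survival(y)
        if len(time) != X.shape[0]:
            raise ValueError("survival data and covariates must align")
        if np.isnan(X).any():
            raise ValueError("missing values in modelled covariates")
        if event.sum() < 2:
            raise ValueError("need at least 2 events to fit a Cox model")

        order = np.argsort(time, kind="stable")
        Xs, ts, ev = X[order], time[order], event[order]

        # standardize for numerical stability; back-transform afterwards
        center = Xs.mean(axis=0)
        scale = Xs.std(axis=0)
        if np.any(scale == 0):
            bad = [self.covariate_names_[i] for i in np.where(scale == 0)[0]]
            raise ValueError(f"constant covariates: {bad}")
        Z = (Xs - center) / scale

        beta = np.zeros(X.shape[1])
        ll, grad, info = self._loglik(beta, Z, ts, ev)
        converged = False
        for _ in range(self.max_iter):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            # step-halving line search
            factor = 1.0
            for _ in range(30):
                new_beta = beta + factor * step
                new_ll, new_grad, new_info = self._loglik(new_beta, Z, ts, ev)
                if new_ll >= ll - 1e-12:
                    break
                factor *= 0.5
            rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            if rel_change < self.tol and np.linalg.norm(grad) < self.grad_tol:
                converged = True
                break
        # monotone likelihood: as beta runs away the gradient decays to zero
        # (so Newton "converges") but the observed information collapses with
        # it -- flag either symptom as separation
        if np.any(np.abs(beta) > 10) or np.linalg.eigvalsh(info).min() < 1e-4:
            raise ConvergenceError(
                "monotone partial likelihood (diverging coefficient / "
                "vanishing information); possible perfect separation. "
                f"standardized beta={np.round(beta, 2)}"
            )
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {self.max_iter} iterations "
                f"(|grad|={np.linalg.norm(grad):.2e})"
            )

        cov_z = np.linalg.inv(info)
        self.coef_ = beta / scale
        self.variance_matrix_ = cov_z / np.outer(scale, scale)
        self.standard_errors_ = np.sqrt(np.diag(self.variance_matrix_))
        self.hazard_ratios_ = np.exp(self.coef_)
        zcrit = stats.norm.ppf(1 - self.alpha / 2)
        self.confidence_intervals_ = np.exp(
            np.column_stack([self.coef_ - zcrit * self.standard_errors_,
                             self.coef_ + zcrit * self.standard_errors_])
        )
        self.z_ = self.coef_ / self.standard_errors_
        self.p_values_ = 2 * stats.norm.sf(np.abs(self.z_))
        self.log_partial_likelihood_ = float(ll)
        self.converged_ = True
        self._fit_state_ = (Z, ts, ev, beta, cov_z, center, scale)
        self.ph_test_ = self._ph_test()
        return self

    def _ph_test(self):
        """Schoenfeld-residual PH check: correlation of scaled residuals
        with event time, per covariate (reported, not enforced)."""
        Z, ts, ev, beta, cov_z, _, _ = self._fit_state_
        w = np.exp(Z @ beta)
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((w[:, None] * Z)[::-1], axis=0)[::-1]
        idx = np.where(ev == 1)[0]
        # residual at each event: observed covariate minus risk-set mean
        resid = Z[idx] - S1[idx] / S0[idx, None]
        d = len(idx)
        scaled = d * resid @ cov_z + beta  # Grambsch-Therneau scaling
        out = {}
        for k, name in enumerate(self.covariate_names_):
            if d > 2 and np.std(scaled[:, k]) > 0 and np.std(ts[idx]) > 0:
                r, p = stats.pearsonr(ts[idx], scaled[:, k])
            else:
                r, p = np.nan, np.nan
            out[name] = {"corr": float(r), "p": float(p)}
        return out

    def predict_linear(self, X):
        """Linear predictor (log relative hazard) at mean-centred covariates."""
        if isinstance(X, pd.DataFrame):
            X = X[self.covariate_names_].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        center = self._fit_state_[5]
        return (X - center) @ self.coef_

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef_,
            "hr": self.hazard_ratios_,
            "se": self.standard_errors_,
            "hr_ci_low": self.confidence_intervals_[:, 0],
            "hr_ci_high": self.confidence_intervals_[:, 1],
            "z": self.z_,
            "p": self.p_values_,
            "ph_p": [self.ph_test_[n]["p"] for n in self.covariate_names_],
        }, index=self.covariate_names_)


def cox_fit(data: pd.DataFrame, covariates, time_col: str = "survival_time",
            event_col: str = "event", ties: str = "efron") -> CoxPHModel:
    """Fit a Cox model on named columns of a phenotype table."""
    covariates = list(covariates)
    missing = [c for c in covariates + [time_col, event_col] if c not in data]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    model = CoxPHModel(ties=ties)
    return model.fit(data[covariates], (data[time_col], data[event_col]))


def relative_risk_percent(fit: CoxPHModel, covariate: str) -> float:
    """Percent change in hazard per unit increase: ``100 * (exp(beta) - 1)``."""
    idx = fit.covariate_names_.index(covariate)
    return float(100.0 * (np.exp(fit.coef_[idx]) - 1.0))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    group_label: str = ""
    all_censored: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival_prob,
            "greenwood_se": self.greenwood_se, "n_at_risk": self.n_at_risk,
            "n_events": self.n_events, "group": self.group_label,
        })


def kaplan_meier(time, event, label: str = "") -> KMCurve:
    time, event = _unpack_survival((time, event))
    if len(time) == 0:
        raise ValueError("empty group")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    surv, se_terms = [], []
    s = 1.0
    gw = 0.0
    at_risk, events = [], []
    for u in uniq:
        n_risk = int(np.sum(t >= u))
        d = int(np.sum((t == u) & (e == 1)))
        s *= 1.0 - d / n_risk
        if n_risk > d:
            gw += d / (n_risk * (n_risk - d))
        else:
            gw = np.inf
        surv.append(s)
        se_terms.append(s * np.sqrt(gw) if np.isfinite(gw) else 0.0)
        at_risk.append(n_risk)
        events.append(d)
    return KMCurve(
        event_times=np.asarray(uniq, float),
        survival_prob=np.asarray(surv, float),
        greenwood_se=np.asarray(se_terms, float),
        n_at_risk=np.asarray(at_risk, int),
        n_events=np.asarray(events, int),
        group_label=label,
        all_censored=len(uniq) == 0,
    )


def tertile_groups(values) -> tuple[np.ndarray, float, float]:
    """Label each subject low/middle/high by the empirical 33.3%/66.7% cuts."""
    values = np.asarray(values, float)
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    labels = np.where(values <= q1, "low", np.where(values > q2, "high", "middle"))
    return labels, float(q1), float(q2)


def km_estimate(data: pd.DataFrame, covariate: str,
                time_col: str = "survival_time", event_col: str = "event",
                drop_middle: bool = True) -> list[KMCurve]:
    """Kaplan-Meier curves for a tertile split on ``covariate``.

    The middle tertile is excluded by default, mirroring a high-vs-low
    contrast of the biomarker.
    """
    labels, _, _ = tertile_groups(data[covariate])
    wanted = ["low", "high"] if drop_middle else ["low", "middle", "high"]
    curves = []
    for lab in wanted:
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"empty tertile group {lab!r}")
        curves.append(kaplan_meier(
            data.loc[mask, time_col], data.loc[mask, event_col],
            label=f"{covariate}:{lab}",
        ))
    return curves


# ---------------------------------------------------------------------------
# AUC comparison
# ---------------------------------------------------------------------------

def binary_auc(scores, labels) -> float:
    """Mann-Whitney AUC of a risk score against a binary outcome."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n1, n0 = int(labels.sum()), int((1 - labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined without both events and non-events")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _placements(scores, labels):
    """DeLong structural components (V10 per case, V01 per control)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    v10 = np.array([(np.sum(xi > y) + 0.5 * np.sum(xi == y)) / len(y) for xi in x])
    v01 = np.array([(np.sum(x > yj) + 0.5 * np.sum(x == yj)) / len(x) for yj in y])
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong z-test for paired (correlated) AUCs; returns (z, two-sided p)."""
    labels = np.asarray(labels).astype(int)
    auc_a = binary_auc(scores_a, labels)
    auc_b = binary_auc(scores_b, labels)
    v10a, v01a = _placements(np.asarray(scores_a, float), labels)
    v10b, v01b = _placements(np.asarray(scores_b, float), labels)
    n1, n0 = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class AUCComparison:
    """Per-model AUCs and DeLong pairwise comparisons."""

    aucs: dict
    pairwise: pd.DataFrame
    model_specs: dict
    fits: dict = field(default_factory=dict)


def model_auc_compare(data: pd.DataFrame, model_specs: list,
                      time_col: str = "survival_time", event_col: str = "event",
                      ties: str = "efron", method: str = "binary",
                      horizon: float | None = None) -> AUCComparison:
    """Fit one Cox model per covariate list and compare their AUCs.

    ``method="binary"`` (default) scores each model's linear predictor
    against deceased-by-ascertainment status; ``method="cumulative_dynamic"``
    instead classifies events by ``horizon`` (cases: event before the
    horizon; controls: followed beyond it; subjects censored earlier are
    dropped). Pairwise p-values use the DeLong test for correlated AUCs.
    """
    if len(model_specs) < 2:
        raise ValueError("need at least two models to compare")
    if data[event_col].sum() == 0:
        raise ValueError("AUC undefined with no events")
    if method == "binary":
        labels = data[event_col].to_numpy(int)
        keep = np.ones(len(data), bool)
    elif method == "cumulative_dynamic":
        if horizon is None:
            horizon = float(data[time_col].max())
        t = data[time_col].to_numpy(float)
        e = data[event_col].to_numpy(int)
        cases = (e == 1) & (t <= horizon)
        controls = t > horizon
        keep = cases | controls
        labels = cases[keep].astype(int)
    else:
        raise ValueError(f"unknown AUC method {method!r}")

    names, scores, specs, fits = [], {}, {}, {}
    for spec in model_specs:
        name = "+".join(spec)
        fit = cox_fit(data, spec, time_col=time_col, event_col=event_col, ties=ties)
        lp = fit.predict_linear(data[spec])
        names.append(name)
        scores[name] = lp[keep]
        specs[name] = list(spec)
        fits[name] = fit
    aucs = {name: binary_auc(scores[name], labels) for name in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            z, p = delong_test(scores[a], scores[b], labels)
            rows.append({"model_a": a, "model_b": b,
                         "auc_a": aucs[a], "auc_b": aucs[b], "z": z, "p": p})
    return AUCComparison(aucs=aucs, pairwise=pd.DataFrame(rows),
                         model_specs=specs, fits=fits)
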