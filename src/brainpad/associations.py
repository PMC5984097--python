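"""Associations of brain-PAD with fitness, morbidity, life-course factors and
molecular ageing markers.

Implements sex-adjusted standardized regressions with Benjamini-Hochberg FDR
control over the five fitness outcomes, the Wilcoxon rank-sum sex contrast
(exact enumeration at small n, midranks and a tie-corrected normal
approximation otherwise), Spearman correlations, the allostatic-load
z-composite, hierarchical variance partitioning (LMG: incremental R^2
averaged over all predictor orderings) and an uncorrected null-association
battery for the morbidity/life-course factors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ALLOSTATIC_COMPONENTS, FITNESS_OUTCOMES

__all__ = [
    "RegressionResult", "standardized_regression", "fitness_association_table",
    "fdr_adjust", "RankTestResult", "rank_sum_test", "spearman",
    "AllostaticLoad", "allostatic_load", "VariancePartition",
    "hierarchical_partition", "null_association_battery",
]


def _zscore(x):
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance variable cannot be standardized")
    return (x - x.mean()) / sd


@dataclass
class RegressionResult:
    outcome: str
    standardized_beta: float
    se: float
    p: float
    n: int
    covariates: tuple
    fdr_significant: bool | None = None
    p_adjusted: float | None = None


def standardized_regression(data: pd.DataFrame, outcome: str,
                            exposure: str = "brain_pad",
                            covariates=("male",)) -> RegressionResult:
    """OLS of a z-scored outcome on the z-scored exposure plus covariates.

    Binary/ordinal covariates enter unstandardized; the reported coefficient
    is the standardized beta on the exposure with a two-sided t-test p-value.
    """
    covariates = tuple(covariates)
    cols = [outcome, exposure, *covariates]
    missing = [c for c in cols if c not in data]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    sub = data[cols].dropna()
    n = len(sub)
    if n <= len(covariates) + 2:
        raise ValueError("too few observations for the requested model")
    y = _zscore(sub[outcome])
    design = np.column_stack(
        [np.ones(n), _zscore(sub[exposure])]
        + [sub[c].to_numpy(float) for c in covariates]
    )
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - design.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = math.sqrt(cov[1, 1])
    tval = coef[1] / se
    p = 2 * stats.t.sf(abs(tval), dof)
    return RegressionResult(
        outcome=outcome, standardized_beta=float(coef[1]), se=float(se),
        p=float(p), n=n, covariates=covariates,
    )


def fdr_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns (significant flags, adjusted p)."""
    p_values = np.asarray(p_values, float)
    if p_values.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, p_adj


def fitness_association_table(data: pd.DataFrame, exposure: str = "brain_pad",
                              covariates=("male",), q: float = 0.05,
                              outcomes=FITNESS_OUTCOMES) -> pd.DataFrame:
    """Sex-adjusted standardized betas for the five fitness outcomes with a
    single FDR family over exactly those five tests."""
    results = [standardized_regression(data, out, exposure, covariates)
               for out in outcomes]
    flags, p_adj = fdr_adjust([r.p for r in results], q=q)
    return pd.DataFrame({
        "outcome": [r.outcome for r in results],
        "standardized_beta": [r.standardized_beta for r in results],
        "se": [r.se for r in results],
        "p": [r.p for r in results],
        "p_fdr": p_adj,
        "fdr_significant": flags,
        "n": [r.n for r in results],
    })


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    """Wilcoxon rank-sum result; W is the rank-sum of the first group."""

    statistic: float
    p: float
    n1: int
    n2: int
    method: str


def _exact_ranksum_p(ranks2, n1, w_obs):
    """Exact two-sided p for the rank-sum with (possibly tied) midranks.

    Uses a subset-sum dynamic programme over doubled midranks (integers), so
    ties are handled without enumerating subsets. Two-sided p is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    n = len(ranks2)
    total = int(ranks2.sum())
    # counts[k][s] = number of k-subsets with doubled rank sum s
    counts = np.zeros((n1 + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        upper = min(n1, n)
        counts[1:upper + 1, r:] += counts[0:upper, :total + 1 - r]
    dist = counts[n1]
    dist /= dist.sum()
    w2 = int(round(2 * w_obs))
    lo = dist[: w2 + 1].sum()
    hi = dist[w2:].sum()
    return float(min(1.0, 2 * min(lo, hi)))


def rank_sum_test(group_a, group_b, exact_limit: int = 12) -> RankTestResult:
    """Wilcoxon rank-sum test of two independent groups.

    Midranks for ties; exact null distribution (DP over rank subsets) when
    both groups have at most ``exact_limit`` members, otherwise a normal
    approximation with continuity and tie correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if n1 <= exact_limit and n2 <= exact_limit:
        p = _exact_ranksum_p(np.round(2 * ranks).astype(int), n1, w)
        method = "exact"
    else:
        mu = n1 * (n1 + n2 + 1) / 2
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12 * ((n + 1) - tie_term)
        if var <= 0:
            return RankTestResult(w, 1.0, n1, n2, "normal")
        z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
        method = "normal"
    return RankTestResult(statistic=w, p=min(1.0, p), n1=n1, n2=n2, method=method)


def spearman(x, y):
    """Spearman rank correlation (Pearson on midranks, t-approximation p).

    Returns ``(rho, p)``; constant input yields ``(nan, nan)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# allostatic load
# ---------------------------------------------------------------------------

@dataclass
class AllostaticLoad:
    composite: np.ndarray
    components: tuple
    directions: dict


def allostatic_load(components: pd.DataFrame,
                    directions: dict | None = None) -> AllostaticLoad:
    """Z-composite allostatic load over the 11 physiological components.

    Each component is z-scored in-sample, multiplied by its direction
    (+1 burden, -1 protective: HDL), averaged, and the mean re-standardized
    to cohort mean 0 / sd 1.
    """
    if directions is None:
        directions = {name: spec[2] for name, spec in ALLOSTATIC_COMPONENTS.items()}
    missing = [c for c in directions if c not in components]
    if missing:
        raise KeyError(f"missing allostatic components: {missing}")
    signed = np.column_stack([
        directions[name] * _zscore(components[name]) for name in directions
    ])
    composite = signed.mean(axis=1)
    return AllostaticLoad(
        composite=_zscore(composite),
        components=tuple(directions),
        directions=dict(directions),
    )


# ---------------------------------------------------------------------------
# hierarchical variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    independent: dict
    joint: dict
    total_r2: float


def _subset_r2(y, X, cols):
    n = len(y)
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return 0.0
    return float(1.0 - resid @ resid / tss)


def hierarchical_partition(data: pd.DataFrame, outcome: str,
                           predictors) -> VariancePartition:
    """LMG hierarchical partitioning of R^2 over <= 8 predictors.

    Fits all 2^k predictor subsets by least squares; each predictor's
    independent contribution is its incremental R^2 averaged over all k!
    orderings (equivalently, over subset sizes). The joint contribution is
    the marginal single-predictor R^2 minus the independent share.
    Independent contributions sum to the full-model R^2.
    """
    predictors = list(predictors)
    k = len(predictors)
    if not 1 <= k <= 8:
        raise ValueError("hierarchical partitioning supports 1-8 predictors; "
                         "fit a subset of predictors instead")
    sub = data[[outcome] + predictors].dropna()
    y = sub[outcome].to_numpy(float)
    X = sub[predictors].to_numpy(float)
    r2 = {}
    for size in range(k + 1):
        for cols in itertools.combinations(range(k), size):
            r2[cols] = _subset_r2(y, X, cols)
    fact = [math.factorial(i) for i in range(k + 1)]
    independent = {}
    for j in range(k):
        others = [i for i in range(k) if i != j]
        contrib = 0.0
        for size in range(k):
            weight = fact[size] * fact[k - size - 1] / fact[k]
            for cols in itertools.combinations(others, size):
                with_j = tuple(sorted(cols + (j,)))
                contrib += weight * (r2[with_j] - r2[cols])
        independent[predictors[j]] = contrib
    joint = {
        predictors[j]: r2[(j,)] - independent[predictors[j]] for j in range(k)
    }
    return VariancePartition(
        independent=independent, joint=joint, total_r2=r2[tuple(range(k))]
    )


# ---------------------------------------------------------------------------
# null-association battery
# ---------------------------------------------------------------------------

DEFAULT_BATTERY_FACTORS = (
    "cvd", "diabetes", "stroke", "hypertension", "apoe_e4",
    "iq11", "social_class", "education_years",
)


def null_association_battery(data: pd.DataFrame,
                             factors=DEFAULT_BATTERY_FACTORS,
                             exposure: str = "brain_pad",
                             covariates=("male",)) -> pd.DataFrame:
    """Sex-adjusted associations of brain-PAD with morbidity and life-course
    factors, reported without multiplicity correction.

    Each row regresses z-scored brain-PAD on the (binary or ordinal) factor
    plus covariates and reports the factor's coefficient and p-value.
    """
    absent = [f for f in factors if f not in data]
    if absent:
        raise KeyError(f"missing battery columns: {absent}")
    rows = []
    for factor in factors:
        sub = data[[exposure, factor, *covariates]].dropna()
        n = len(sub)
        y = _zscore(sub[exposure])
        design = np.column_stack(
            [np.ones(n), sub[factor].to_numpy(float)]
            + [sub[c].to_numpy(float) for c in covariates]
        )
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = n - design.shape[1]
        cov = (resid @ resid / dof) * np.linalg.inv(design.T @ design)
        se = math.sqrt(cov[1, 1])
        p = 2 * stats.t.sf(abs(coef[1] / se), dof) if se > 0 else np.nan
        rows.append({"factor": factor, "beta": float(coef[1]), "se": float(se),
                     "p": float(p), "n": n})
    return pd.DataFrame(rows)
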