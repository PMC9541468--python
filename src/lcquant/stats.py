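"""Group-level classical statistics.

ANCOVA with Tukey-Kramer post hocs, pooled-variance t tests (with a
summary-statistic entry point so printed tables can be re-analysed),
Pearson chi-square without continuity correction, Cramer's V, Bonferroni
and Holm multiplicity adjustments, and simple linear/quadratic
regressions.

Conventions were fixed by recomputation of the published demographics
table: pooled-variance (not Welch) t tests and Pearson chi-square
without Yates correction reproduce the printed p values, Welch and Yates
do not.  Welch remains available behind a flag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "ancova_group",
    "two_sample_t",
    "two_sample_t_summary",
    "chi_square",
    "cramers_v",
    "adjust_p",
    "bonferroni_threshold",
    "simple_regression",
    "tukey_pairwise",
]


@dataclass
class TestResult:
    statistic: str  # "F", "t", "chi2"
    value: float
    df: tuple[float, ...]
    p: float
    effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or math.isnan(self.p)):
            raise ValueError("p value outside [0, 1]")


def two_sample_t_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> TestResult:
    """Independent two-sample t test from summary statistics.

    Pooled variance by default (df = n1 + n2 - 2); Welch optional.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    v1, v2 = sd1**2, sd2**2
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    if se2 == 0:
        t = 0.0
    else:
        t = (mean1 - mean2) / math.sqrt(se2)
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult("t", float(t), (float(df),), float(p))


def two_sample_t(x, y, welch: bool = False) -> TestResult:
    """Independent two-sample t test from raw vectors.

    Defined through the summary-statistic path, so both entry points
    agree to machine precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    return two_sample_t_summary(
        float(np.mean(x)), float(np.std(x, ddof=1)), len(x),
        float(np.mean(y)), float(np.std(y, ddof=1)), len(y),
        welch=welch,
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    n = table.sum()
    r, c = table.shape
    v = cramers_v(float(chi2), int(n), (r, c))
    return TestResult("chi2", float(chi2), (float(df),), float(p), {"cramers_v": v})


def cramers_v(chi2: float, n: int, table_dims: tuple[int, int]) -> float:
    """V = sqrt(chi2 / (n * min(r-1, c-1)))."""
    if chi2 < 0 or n < 1:
        raise ValueError("chi2 must be >= 0 and n >= 1")
    r, c = table_dims
    return math.sqrt(chi2 / (n * min(r - 1, c - 1)))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def adjust_p(p_values, method: str = "holm"):
    """Holm step-down (or plain Bonferroni) adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown method {method!r}")


def _check_collinearity(X: np.ndarray) -> None:
    # condition-number guard on the scaled design
    Xs = X / np.maximum(np.linalg.norm(X, axis=0), 1e-300)
    if np.linalg.cond(Xs) > 1e8:
        raise ValueError("design is (nearly) collinear; check covariates")


def tukey_pairwise(
    means: dict[str, float],
    cov: pd.DataFrame,
    ns: dict[str, int],
    df_resid: float,
) -> pd.DataFrame:
    """Tukey-Kramer comparisons of (adjusted) group means.

    ``cov`` holds the sampling covariance of the mean estimates.  The
    studentized-range p value uses q = |diff| / SE * sqrt(2), which for
    unequal group sizes is the Tukey-Kramer form.
    """
    k = len(means)
    rows = []
    for a, b in itertools.combinations(sorted(means), 2):
        diff = means[a] - means[b]
        se = math.sqrt(cov.loc[a, a] + cov.loc[b, b] - 2 * cov.loc[a, b])
        q = abs(diff) / se * math.sqrt(2)
        p = float(sps.studentized_range.sf(q, k, df_resid))
        rows.append({"group1": a, "group2": b, "diff": diff, "se": se,
                     "q": q, "p_tukey": min(p, 1.0)})
    return pd.DataFrame(rows)


def ancova_group(
    y, groups, covariates: pd.DataFrame | None = None
) -> tuple[TestResult, pd.DataFrame]:
    """ANCOVA: outcome ~ group + covariates, type-II F for group.

    Returns the group F test (adjusting for the covariates of no
    interest) and Tukey-Kramer pairwise comparisons of the
    covariate-adjusted group means.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("ANCOVA needs at least 2 groups")
    for g in levels:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")

    # design: intercept + group dummies (first level reference) + covariates
    n = len(y)
    G = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    cov_arr = np.empty((n, 0))
    cov_names: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        cov_arr = np.asarray(covariates, dtype=float)
        cov_names = list(covariates.columns)
    keep = ~np.isnan(y)
    if cov_arr.size:
        keep &= ~np.isnan(cov_arr).any(axis=1)
    y, G, groups = y[keep], G[keep], groups[keep]
    cov_arr = cov_arr[keep]
    n = len(y)

    X_full = np.column_stack([np.ones(n), G, cov_arr])
    _check_collinearity(X_full)
    full = sm.OLS(y, X_full).fit()
    X_red = np.column_stack([np.ones(n), cov_arr])
    red = sm.OLS(y, X_red).fit()
    df_num = len(levels) - 1
    df_den = n - X_full.shape[1]
    f = (red.ssr - full.ssr) / df_num / (full.ssr / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    result = TestResult("F", float(f), (float(df_num), float(df_den)), p)

    # covariate-adjusted means: prediction at grand covariate means
    cov_mean = cov_arr.mean(axis=0) if cov_arr.size else np.empty(0)
    means, weights = {}, {}
    for g in levels:
        w = np.zeros(X_full.shape[1])
        w[0] = 1.0
        if g != levels[0]:
            w[1 + levels[1:].index(g)] = 1.0
        w[1 + len(levels) - 1:] = cov_mean
        means[g] = float(w @ full.params)
        weights[g] = w
    W = np.column_stack([weights[g] for g in levels])
    cov_means = pd.DataFrame(
        W.T @ full.cov_params() @ W, index=levels, columns=levels
    )
    ns = {g: int((groups == g).sum()) for g in levels}
    posthoc = tukey_pairwise(means, cov_means, ns, df_den)
    return result, posthoc


def one_way_anova(y, groups) -> TestResult:
    """Plain one-way ANOVA (no covariates)."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(y)
    y, groups = y[keep], groups[keep]
    levels = sorted(set(groups.tolist()))
    samples = [y[groups == g] for g in levels]
    f, p = sps.f_oneway(*samples)
    df1 = len(levels) - 1
    df2 = len(y) - len(levels)
    return TestResult("F", float(f), (float(df1), float(df2)), float(p))


def simple_regression(y, x, degree: int = 1) -> TestResult:
    """OLS of y on polynomial(x, degree): overall F, R-squared, p."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    if len(y) < degree + 2:
        raise ValueError("too few points for the requested degree")
    X = np.column_stack([np.ones(len(x))] + [x**d for d in range(1, degree + 1)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant predictor?)")
    fit = sm.OLS(y, X).fit()
    return TestResult(
        "F",
        float(fit.fvalue),
        (float(fit.df_model), float(fit.df_resid)),
        float(fit.f_pvalue),
        {"r2": float(fit.rsquared),
         "beta": float(fit.params[1]),
         "se": float(fit.bse[1])},
    )
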