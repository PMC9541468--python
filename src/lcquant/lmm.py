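"""Clinical-correlation mixed-effect model.

The model regresses stacked LC CNR values (three repeated outcomes per
patient: whole, left and right LC) on a clinical score, diagnostic group
(PD vs PSP, PD as reference), their interaction, and the LC-definition
factor, with a subject random intercept:

    CNR ~ score * group + lc_definition + (1 | subject)

Healthy controls are excluded: the clinical hypothesis concerns patient
groups.  Score and outcome are z-scored over the modelled sample by
default so slopes are unitless standardized coefficients.

The fit maximises the restricted likelihood (REML); the random-intercept
model has closed-form block algebra, so the profile over the variance
ratio is optimised directly.  Denominator degrees of freedom for the
F/t tests use the Satterthwaite approximation: with three balanced
repeats per subject this lands at (number of subjects - between-subject
parameters), matching the familiar F(1, n-4)-style reporting.  When the
random-intercept variance collapses to zero the fit falls back to OLS
with cluster-robust (by subject) standard errors and is flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .cnr import CNRSummary
from .core import SubjectRecord

__all__ = [
    "LmmResult",
    "stack_cnr",
    "standardize_inputs",
    "fit_clinical_lmm",
]

LC_DEFINITIONS = ("whole", "left", "right")


@dataclass
class TermStats:
    beta: float
    se: float
    t: float
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class LmmResult:
    terms: dict[str, TermStats]
    slopes: dict[str, TermStats]  # per-group simple slopes
    var_subject: float
    var_residual: float
    beta: pd.Series
    n_subjects: int
    n_rows: int
    fallback: str | None = None  # "ols_cluster_robust" when singular
    standardized: bool = True


def stack_cnr(
    summaries: list[CNRSummary],
    records: list[SubjectRecord],
    score: str,
    groups: tuple[str, ...] = ("PD", "PSP"),
) -> pd.DataFrame:
    """Long-format table: one row per subject x LC definition.

    Subjects outside ``groups`` or with a missing score are dropped
    (listwise deletion per model).
    """
    by_id = {r.id: r for r in records}
    rows = []
    for s in summaries:
        rec = by_id.get(s.subject_id)
        if rec is None or rec.group not in groups:
            continue
        val = rec.score(score)
        if math.isnan(val):
            continue
        for lc_def in LC_DEFINITIONS:
            rows.append(
                {
                    "id": s.subject_id,
                    "group": rec.group,
                    "score": val,
                    "lc_definition": lc_def,
                    "cnr": s.values[lc_def],
                }
            )
    return pd.DataFrame(rows)


def standardize_inputs(
    data: pd.DataFrame, columns: tuple[str, ...] = ("score", "cnr")
) -> pd.DataFrame:
    """z-score numeric columns over the modelled sample (ddof=1)."""
    out = data.copy()
    for c in columns:
        sd = out[c].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"column {c!r} has zero variance")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def _build_design(data: pd.DataFrame, ref_group: str = "PD"):
    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        raise ValueError("the clinical model compares exactly two groups")
    other = [g for g in groups if g != ref_group]
    if not other:
        ref_group, other = groups[0], [groups[1]]
    alt = other[0]
    g_ind = (data["group"] == alt).astype(float).to_numpy()
    score = data["score"].to_numpy(dtype=float)
    cols = {
        "intercept": np.ones(len(data)),
        "score": score,
        f"group[{alt}]": g_ind,
        f"score:group[{alt}]": score * g_ind,
    }
    for lc_def in LC_DEFINITIONS[1:]:
        cols[f"lc[{lc_def}]"] = (data["lc_definition"] == lc_def).astype(float).to_numpy()
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), ref_group, alt


class _RandomInterceptREML:
    """Closed-form REML machinery for y = X b + (1|subject) + e."""

    def __init__(self, y, X, subject_ids):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        codes, _ = pd.factorize(np.asarray(subject_ids))
        self.blocks = [np.flatnonzero(codes == k) for k in range(codes.max() + 1)]
        self.n, self.p = self.X.shape

    def _gls_parts(self, lam: float):
        # X' Vt^-1 X, X' Vt^-1 y, y' Vt^-1 y with Vt = I + lam * J per block
        XtX = np.zeros((self.p, self.p))
        Xty = np.zeros(self.p)
        yty = 0.0
        logdet_v = 0.0
        for idx in self.blocks:
            Xi, yi = self.X[idx], self.y[idx]
            ni = len(idx)
            w = lam / (1.0 + ni * lam)
            sx, sy = Xi.sum(axis=0), yi.sum()
            XtX += Xi.T @ Xi - w * np.outer(sx, sx)
            Xty += Xi.T @ yi - w * sx * sy
            yty += yi @ yi - w * sy * sy
            logdet_v += math.log1p(ni * lam)
        return XtX, Xty, yty, logdet_v

    def profile_neg2_reml(self, lam: float) -> float:
        XtX, Xty, yty, logdet_v = self._gls_parts(lam)
        sign, logdet_x = np.linalg.slogdet(XtX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtX, Xty)
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        nmp = self.n - self.p
        if rss <= 0:
            return np.inf
        sigma_e2 = rss / nmp
        return nmp * math.log(sigma_e2) + logdet_v + logdet_x + nmp

    def neg2_reml(self, sigma_b2: float, sigma_e2: float) -> float:
        """Unprofiled -2 restricted log-likelihood (up to a constant)."""
        if sigma_e2 <= 0 or sigma_b2 < 0:
            return np.inf
        lam = sigma_b2 / sigma_e2
        XtX, Xty, yty, logdet_v = self._gls_parts(lam)
        sign, logdet_x = np.linalg.slogdet(XtX / sigma_e2)
        beta = np.linalg.solve(XtX, Xty)
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        return (
            (self.n - 0) * 0.0
            + self.n * math.log(sigma_e2)
            + logdet_v
            + logdet_x
            + rss / sigma_e2
        )

    def fit(self):
        res = optimize.minimize_scalar(
            lambda u: self.profile_neg2_reml(math.exp(u)),
            bounds=(-12.0, 8.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = math.exp(res.x)
        if self.profile_neg2_reml(0.0) <= res.fun:
            lam = 0.0
        XtX, Xty, yty, _ = self._gls_parts(lam)
        beta = np.linalg.solve(XtX, Xty)
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        sigma_e2 = rss / (self.n - self.p)
        sigma_b2 = lam * sigma_e2
        cov_beta = sigma_e2 * np.linalg.inv(XtX)
        return beta, cov_beta, sigma_b2, sigma_e2

    def contrast_variance(self, c, sigma_b2, sigma_e2) -> float:
        lam = sigma_b2 / sigma_e2
        XtX, _, _, _ = self._gls_parts(lam)
        return float(sigma_e2 * c @ np.linalg.solve(XtX, c))

    def satterthwaite_df(self, c, sigma_b2, sigma_e2) -> float:
        """df = 2 f^2 / Var(f), f = Var(c'beta), via the delta method."""
        theta = np.array([sigma_b2, sigma_e2])
        steps = np.maximum(1e-4 * np.abs(theta), 1e-8)

        def f(th):
            b2 = max(th[0], 0.0)
            return self.contrast_variance(c, b2, th[1])

        grad = np.zeros(2)
        for k in range(2):
            e = np.zeros(2)
            e[k] = steps[k]
            grad[k] = (f(theta + e) - f(theta - e)) / (2 * steps[k])

        def nll(th):
            return 0.5 * self.neg2_reml(max(th[0], 0.0), th[1])

        H = np.zeros((2, 2))
        for a in range(2):
            for b in range(2):
                ea = np.zeros(2); ea[a] = steps[a]
                eb = np.zeros(2); eb[b] = steps[b]
                H[a, b] = (
                    nll(theta + ea + eb) - nll(theta + ea - eb)
                    - nll(theta - ea + eb) + nll(theta - ea - eb)
                ) / (4 * steps[a] * steps[b])
        try:
            cov_theta = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(self.n - self.p)
        var_f = float(grad @ cov_theta @ grad)
        fval = f(theta)
        if var_f <= 0 or fval <= 0:
            return float(self.n - self.p)
        df = 2 * fval**2 / var_f
        return float(min(max(df, 1.0), self.n - self.p))


def _term_stats(beta, cov, c, df_den) -> TermStats:
    est = float(c @ beta)
    se = math.sqrt(float(c @ cov @ c))
    t = est / se
    p = 2 * float(sps.t.sf(abs(t), df_den))
    return TermStats(est, se, t, t * t, 1.0, float(df_den), p)


def fit_clinical_lmm(
    data: pd.DataFrame,
    standardize: bool = True,
    ref_group: str = "PD",
    alpha: float = 0.05,
    singular_tol: float = 1e-8,
) -> LmmResult:
    """Fit the clinical-correlation random-intercept model.

    ``data`` is long format with columns id, group, score,
    lc_definition, cnr (see :func:`stack_cnr`).  Reports marginal tests
    for the score main effect (slope averaged over groups) and the
    score x group interaction, plus per-group simple slopes, all with
    Satterthwaite denominator degrees of freedom.
    """
    counts = data.groupby("group")["id"].nunique()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 groups with >= 3 subjects each")
    per_subj = data.groupby("id").size()
    if (per_subj != len(LC_DEFINITIONS)).any():
        raise ValueError("each subject must contribute exactly 3 outcome rows")

    if standardize:
        data = standardize_inputs(data)
    X, names, ref, alt = _build_design(data, ref_group)
    model = _RandomInterceptREML(data["cnr"].to_numpy(), X, data["id"].to_numpy())
    beta, cov_beta, sigma_b2, sigma_e2 = model.fit()

    fallback = None
    if sigma_b2 <= singular_tol * max(sigma_e2, 1e-300):
        fallback = "ols_cluster_robust"
        warnings.warn(
            "random-intercept variance is ~0; falling back to OLS with "
            "cluster-robust (subject) standard errors",
            stacklevel=2,
        )
        import statsmodels.api as sm

        ols = sm.OLS(data["cnr"].to_numpy(), X).fit(
            cov_type="cluster", cov_kwds={"groups": data["id"].to_numpy()}
        )
        beta = np.asarray(ols.params)
        cov_beta = np.asarray(ols.cov_params())
        sigma_b2 = 0.0
        sigma_e2 = float(ols.mse_resid)

    i_score = names.index("score")
    i_int = names.index(f"score:group[{alt}]")
    p = len(names)

    def contrast(weights: dict[int, float]) -> np.ndarray:
        c = np.zeros(p)
        for k, v in weights.items():
            c[k] = v
        return c

    n_subj = int(data["id"].nunique())

    def df_for(c) -> float:
        if fallback:
            return float(n_subj - 4)  # between-subject parameters: 4
        return model.satterthwaite_df(c, sigma_b2, sigma_e2)

    # marginal score effect: slope averaged over the two groups
    c_main = contrast({i_score: 1.0, i_int: 0.5})
    c_int = contrast({i_int: 1.0})
    c_group = contrast({names.index(f"group[{alt}]"): 1.0})
    terms = {
        "score": _term_stats(beta, cov_beta, c_main, df_for(c_main)),
        "score_x_group": _term_stats(beta, cov_beta, c_int, df_for(c_int)),
        "group": _term_stats(beta, cov_beta, c_group, df_for(c_group)),
    }
    slopes = {
        ref: _term_stats(beta, cov_beta, contrast({i_score: 1.0}),
                         df_for(contrast({i_score: 1.0}))),
        alt: _term_stats(beta, cov_beta, contrast({i_score: 1.0, i_int: 1.0}),
                         df_for(contrast({i_score: 1.0, i_int: 1.0}))),
    }
    return LmmResult(
        terms=terms,
        slopes=slopes,
        var_subject=float(sigma_b2),
        var_residual=float(sigma_e2),
        beta=pd.Series(beta, index=names),
        n_subjects=n_subj,
        n_rows=len(data),
        fallback=fallback,
        standardized=standardize,
    )
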