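"""Lateralization analyses: LC contrast asymmetry vs motor asymmetry.

The asymmetry index AI = (right - left) / (right + left) captures the
degree and direction of lateralization for whole-LC contrast and for
lateralized motor severity.  Categorical lateralization cross-tabulates
the side of lower LC contrast ("atrophy side") per subregion against
the side of higher weighted motor score, tested by Pearson chi-square
with Cramer's V.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import TestResult, chi_square

__all__ = [
    "AsymmetryRecord",
    "asymmetry_index",
    "lateralization",
    "lateralization_table",
    "ai_regression",
]


@dataclass
class AsymmetryRecord:
    subject_id: str
    ai_lc: float
    ai_motor: float
    lat_lc: dict[str, str]  # per-subregion atrophy side
    lat_motor: str


def asymmetry_index(right: float, left: float) -> float:
    """(right - left) / (right + left)."""
    denom = right + left
    if denom == 0:
        raise ZeroDivisionError("right + left must be non-zero")
    return (right - left) / denom


def lateralization(left_value: float, right_value: float, lower_is_affected: bool = True) -> str:
    """Side label; ties go to 'right' with a warning (convention)."""
    if left_value == right_value:
        warnings.warn("tied sides; assigning 'right' by convention", stacklevel=2)
        return "right"
    if lower_is_affected:
        return "left" if left_value < right_value else "right"
    return "left" if left_value > right_value else "right"


def lateralization_table(
    lat_lc: list[str], lat_motor: list[str]
) -> tuple[pd.DataFrame, TestResult | None]:
    """2x2 cross-tabulation of LC-atrophy side vs motor-affected side.

    Returns the count table and the chi-square result (with Cramer's V
    in ``effect``); a degenerate margin yields the table with a warning
    and no test.
    """
    if len(lat_lc) != len(lat_motor) or len(lat_lc) == 0:
        raise ValueError("need paired, non-empty side labels")
    tab = pd.crosstab(
        pd.Series(lat_lc, name="lc_side"), pd.Series(lat_motor, name="motor_side")
    ).reindex(index=["left", "right"], columns=["left", "right"], fill_value=0)
    counts = tab.to_numpy()
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        warnings.warn("degenerate margin; reporting table without test", stacklevel=2)
        return tab, None
    return tab, chi_square(counts)


def ai_regression(ai_motor, ai_lc) -> TestResult:
    """OLS of motor AI on LC AI: R^2, F, two-sided p."""
    y = np.asarray(ai_motor, dtype=float)
    x = np.asarray(ai_lc, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    if len(y) < 4:
        raise ValueError("need at least 4 AI pairs")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    fit = sm.OLS(y, np.column_stack([np.ones(len(x)), x])).fit()
    return TestResult(
        "F",
        float(fit.fvalue),
        (float(fit.df_model), float(fit.df_resid)),
        float(fit.f_pvalue),
        {"r2": float(fit.rsquared),
         "beta": float(fit.params[1]),
         "se": float(fit.bse[1])},
    )


def build_asymmetry_records(
    summaries,
    records,
    subregion_sides: dict[str, dict[str, tuple[float, float]]],
    group: str = "PD",
) -> list[AsymmetryRecord]:
    """Assemble per-subject asymmetry records for one patient group.

    ``subregion_sides`` maps subject id -> subregion ->
    (left mean CNR, right mean CNR).  Motor sides come from the
    pre-computed UPDRS-III-left / UPDRS-III-right columns.
    """
    by_id = {r.id: r for r in records}
    out = []
    for s in summaries:
        rec = by_id.get(s.subject_id)
        if rec is None or rec.group != group:
            continue
        ml = rec.score("UPDRS-III-left")
        mr = rec.score("UPDRS-III-right")
        if math.isnan(ml) or math.isnan(mr) or (ml + mr) == 0:
            continue
        sides = subregion_sides.get(s.subject_id, {})
        lat_lc = {
            region: lateralization(lv, rv)
            for region, (lv, rv) in sides.items()
        }
        out.append(
            AsymmetryRecord(
                subject_id=s.subject_id,
                ai_lc=asymmetry_index(s.values["right"], s.values["left"]),
                ai_motor=asymmetry_index(mr, ml),
                lat_lc=lat_lc,
                lat_motor=lateralization(ml, mr, lower_is_affected=False),
            )
        )
    return out
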