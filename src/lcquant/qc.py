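"""Registration-accuracy and signal-quality indices.

Dice similarity (DSC) between each subject's coregistered pons mask and
the shared template pons mask proxies registration accuracy; regional
SNR (mean / sample SD of the raw MT signal) proxies signal quality.
Both feed the group analyses as covariates of no interest, and the QA
report tests that neither differs by group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .core import RegionMask, VolumeGrid

__all__ = ["DiceResult", "dice", "mask_volume", "qa_report"]


@dataclass
class DiceResult:
    dsc: float
    n_a: int
    n_b: int
    n_intersection: int


def dice(a: RegionMask, b: RegionMask) -> DiceResult:
    """DSC = 2|A ∩ B| / (|A| + |B|) for two binary masks on one grid."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both masks must be non-empty")
    fa = np.ravel_multi_index(a.voxels.T, a.shape)
    fb = np.ravel_multi_index(b.voxels.T, b.shape)
    inter = len(np.intersect1d(fa, fb, assume_unique=True))
    return DiceResult(
        dsc=2 * inter / (len(a) + len(b)),
        n_a=len(a),
        n_b=len(b),
        n_intersection=inter,
    )


def mask_volume(mask: RegionMask, grid: VolumeGrid) -> float:
    """Mask volume in mm^3: voxel count x voxel volume."""
    if mask.shape != grid.shape:
        raise ValueError("mask and grid shapes differ")
    return len(mask) * grid.voxel_volume_mm3


def _manual_mixed_anova(long: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way mixed ANOVA by direct sum-of-squares decomposition."""
    grand = long["snr"].mean()
    n_region = long["subregion"].nunique()
    n_subj = long["id"].nunique()
    n_group = long["group"].nunique()
    subj_mean = long.groupby("id")["snr"].mean()
    group_of = long.groupby("id")["group"].first()
    group_mean = long.groupby("group")["snr"].mean()
    region_mean = long.groupby("subregion")["snr"].mean()
    cell_mean = long.groupby(["group", "subregion"])["snr"].mean()

    ss_group = n_region * sum(
        (group_mean[group_of[s]] - grand) ** 2 for s in subj_mean.index
    )
    ss_subj_within = n_region * sum(
        (subj_mean[s] - group_mean[group_of[s]]) ** 2 for s in subj_mean.index
    )
    ss_region = n_subj * ((region_mean - grand) ** 2).sum()
    ss_inter = 0.0
    for (g, r), m in cell_mean.items():
        n_g = (group_of == g).sum()
        ss_inter += n_g * (m - group_mean[g] - region_mean[r] + grand) ** 2
    ss_total = ((long["snr"] - grand) ** 2).sum()
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_region - ss_inter

    df_group = n_group - 1
    df_subj = n_subj - n_group
    df_region = n_region - 1
    df_inter = df_group * df_region
    df_err = df_subj * df_region

    def _row(src, ss, df1, df2, ss_err, include_eps):
        ms, ms_e = ss / df1, ss_err / max(df2, 1)
        f = ms / ms_e if ms_e > 0 else (np.inf if ms > 1e-12 else np.nan)
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else (0.0 if f == np.inf else np.nan)
        return {"Source": src, "SS": ss, "DF1": df1, "DF2": df2, "MS": ms,
                "F": f, "p_unc": p, "np2": np.nan,
                "eps": 1.0 if include_eps else np.nan}

    return pd.DataFrame(
        [
            _row("group", ss_group, df_group, df_subj, ss_subj_within, False),
            _row("subregion", ss_region, df_region, df_err, ss_err_within, True),
            _row("Interaction", ss_inter, df_inter, df_err, ss_err_within, False),
        ]
    )


def qa_report(qa_table: pd.DataFrame, gg_correction: bool = False) -> dict:
    """QA statistics across groups.

    Expects one row per subject with columns ``id``, ``group``, ``dsc``,
    ``pons_volume`` and ``snr_rostral`` / ``snr_central`` / ``snr_caudal``.
    Returns per-group descriptives, one-way ANOVAs on DSC and pons
    volume, and a mixed (repeated-measures) ANOVA on SNR with subregion
    as the within factor and group as the between factor, with
    Bonferroni-corrected pairwise post hocs.  ``gg_correction`` switches
    the within-factor test to the Greenhouse-Geisser corrected p value
    (the uncorrected, sphericity-assumed F is reported either way).
    """
    groups = sorted(qa_table["group"].unique())
    if len(groups) < 2:
        raise ValueError("QA report requires at least 2 groups")
    counts = qa_table.groupby("group").size()
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 subjects")

    def _safe_oneway(samples):
        """One-way ANOVA with exact-null guard (F=0, p=1 when SSB ~ 0)."""
        all_vals = np.concatenate(samples)
        grand = all_vals.mean()
        ssb = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
        sst = float(((all_vals - grand) ** 2).sum())
        if ssb <= 1e-12 * max(sst, 1e-300):
            return 0.0, 1.0
        f, p = sps.f_oneway(*samples)
        return float(f), float(p)

    metrics = [c for c in ("dsc", "pons_volume") if c in qa_table.columns]
    descriptives = (
        qa_table.groupby("group")[
            metrics + [c for c in qa_table.columns if c.startswith("snr_")]
        ]
        .agg(["mean", "std"])
    )

    out: dict = {"descriptives": descriptives, "groups": groups}
    for metric in metrics:
        samples = [
            qa_table.loc[qa_table["group"] == g, metric].dropna().to_numpy()
            for g in groups
        ]
        f, p = _safe_oneway(samples)
        out[f"anova_{metric}"] = {
            "F": float(f),
            "df": (len(groups) - 1, int(sum(len(s) for s in samples)) - len(groups)),
            "p": float(p),
        }

    snr_cols = [c for c in qa_table.columns if c.startswith("snr_")]
    if snr_cols:
        long = qa_table.melt(
            id_vars=["id", "group"],
            value_vars=snr_cols,
            var_name="subregion",
            value_name="snr",
        )
        long["subregion"] = long["subregion"].str.replace("snr_", "", regex=False)
        try:
            aov = pg.mixed_anova(
                long, dv="snr", within="subregion", between="group", subject="id"
            )
        except Exception:
            # degenerate (zero within-cell error) data break the library fit;
            # fall back to an explicit balanced two-way mixed decomposition
            aov = _manual_mixed_anova(long)
        rows = {}
        for _, r in aov.iterrows():
            term = str(r["Source"]).lower()
            key = {"group": "group", "subregion": "subregion", "interaction": "interaction"}[term]
            p_val = r["p_unc"]
            f_val = r["F"]
            # Greenhouse-Geisser: rescale both df by the epsilon estimate
            p_gg = None
            eps = r.get("eps")
            if key in ("subregion", "interaction") and pd.notna(eps) and np.isfinite(f_val):
                p_gg = float(
                    sps.f.sf(f_val, r["DF1"] * eps, r["DF2"] * eps)
                )
            if gg_correction and p_gg is not None:
                p_val = p_gg
            if not np.isfinite(f_val) and "SS" in aov.columns and abs(r["SS"]) <= 1e-12:
                f_val, p_val = 0.0, 1.0  # exactly-null effect with zero error SS
            rows[key] = {
                "F": float(f_val),
                "df": (float(r["DF1"]), float(r["DF2"])),
                "p": float(p_val),
                "p_gg": p_gg,
            }
        out["snr_anova"] = rows
        try:
            out["snr_posthoc_subregion"] = pg.pairwise_tests(
                data=long, dv="snr", within="subregion", subject="id",
                padjust="bonf",
            )[["A", "B", "T", "dof", "p_corr"]]
            out["snr_posthoc_group"] = pg.pairwise_tests(
                data=long.groupby(["id", "group"], as_index=False)["snr"].mean(),
                dv="snr", between="group", padjust="bonf",
            )[["A", "B", "T", "dof", "p_corr"]]
        except Exception:
            out["snr_posthoc_subregion"] = None
            out["snr_posthoc_group"] = None
    return out
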