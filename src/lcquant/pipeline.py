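"""End-to-end orchestration: simulate -> CNR -> QA -> statistics -> report.

Each stage is a plain function over in-memory objects so it can be
re-run from persisted intermediates; :func:`run_pipeline` chains them,
writes every table as TSV, and records a run manifest (seed, config,
package versions, stage wall times).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import ai_regression, build_asymmetry_records, lateralization_table
from .cnr import (
    cnr_map,
    reference_box_mask,
    reference_stats,
    regional_cnr,
    snr,
    split_hemispheres,
    split_subregions,
    threshold_atlas,
)
from .core import RegionMask, SubjectRecord, VolumeGrid, records_to_frame
from .lmm import fit_clinical_lmm, stack_cnr
from .qc import dice, mask_volume, qa_report
from .stats import ancova_group, bonferroni_threshold
from .synthetic import SUBREGIONS, Cohort, SimulationConfig, make_cohort, write_cohort
from .voxelwise import TfceParams, permutation_fwe, smooth_cnr

__all__ = ["PipelineConfig", "CohortMeasures", "extract_cohort_measures", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "lcquant_run"
    seed: int = 0
    atlas_threshold: float = 0.05
    smooth_fwhm_mm: float = 1.0
    alpha: float = 0.05
    n_models: int = 3  # Bonferroni family: three clinical LMMs
    n_subregion_models: int = 3  # Bonferroni family: three subregional ANCOVAs
    lmm_scores: tuple[str, ...] = ("MoCA", "ACE-R", "AS")
    tfce: TfceParams = field(default_factory=TfceParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        tfce = TfceParams(**raw.pop("tfce", {}))
        cfg = cls(simulation=sim, tfce=tfce, **raw)
        cfg.simulation.seed = cfg.seed
        cfg.tfce.seed = cfg.seed
        return cfg


@dataclass
class CohortMeasures:
    """All per-subject measurements the statistical stages consume."""

    summaries: list
    summary_df: pd.DataFrame
    qa_df: pd.DataFrame
    records: list[SubjectRecord]
    Y: np.ndarray  # (n_subjects, n_mask_voxels) smoothed masked CNR
    subject_order: list[str]
    mask: RegionMask
    grid: VolumeGrid
    subregion_sides: dict[str, dict[str, tuple[float, float]]]


def extract_cohort_measures(
    cohort: Cohort,
    atlas_threshold: float = 0.05,
    smooth_fwhm_mm: float = 1.0,
) -> CohortMeasures:
    """CNR summaries, QA indices and smoothed voxel matrices for a cohort."""
    grid = cohort.grid
    lc_mask = threshold_atlas(cohort.atlas, atlas_threshold)
    ref_box = reference_box_mask(grid, cohort.ref_center_mm)
    rostral, central, caudal = split_subregions(lc_mask)
    sub_masks = dict(zip(SUBREGIONS, (rostral, central, caudal)))
    side_masks = {
        name: split_hemispheres(m, grid) for name, m in sub_masks.items()
    }

    summaries, qa_rows, rowsY, order = [], [], [], []
    sides: dict[str, dict[str, tuple[float, float]]] = {}
    idx = tuple(lc_mask.voxels.T)
    for rec in cohort.records:
        vol = cohort.volumes[rec.id]
        ref = reference_stats(vol, ref_box)
        cmap = cnr_map(vol, ref)
        summary = regional_cnr(cmap, rec.id, lc_mask, grid)
        summaries.append(summary)
        smoothed = smooth_cnr(cmap, smooth_fwhm_mm, lc_mask)
        rowsY.append(smoothed.data[idx])
        order.append(rec.id)

        qa = {"id": rec.id, "group": rec.group}
        qa["dsc"] = dice(cohort.pons_individual[rec.id], cohort.pons_template).dsc
        qa["pons_volume"] = mask_volume(cohort.pons_individual[rec.id], grid)
        for name, m in sub_masks.items():
            qa[f"snr_{name}"] = snr(vol, m, name).snr
        qa["snr_whole"] = snr(vol, lc_mask, "whole").snr
        qa_rows.append(qa)
        rec.qa = {k: v for k, v in qa.items() if k not in ("id", "group")}

        sides[rec.id] = {
            name: (
                float(np.mean(lm.values_from(cmap))),
                float(np.mean(rm.values_from(cmap))),
            )
            for name, (lm, rm) in side_masks.items()
        }

    summary_df = pd.DataFrame(
        [{"id": s.subject_id, "group": rec.group, **s.values}
         for s, rec in zip(summaries, cohort.records)]
    )
    return CohortMeasures(
        summaries=summaries,
        summary_df=summary_df,
        qa_df=pd.DataFrame(qa_rows),
        records=cohort.records,
        Y=np.vstack(rowsY),
        subject_order=order,
        mask=lc_mask,
        grid=grid,
        subregion_sides=sides,
    )


def cohort_voxel_matrix(
    cohort: Cohort,
    atlas_threshold: float = 0.05,
    smooth_fwhm_mm: float = 1.0,
) -> tuple[np.ndarray, RegionMask, list[str]]:
    """Smoothed, masked CNR values at LC voxels: (n_subjects, n_voxels).

    Lean path for voxelwise simulation studies (no QA indices).
    """
    mask = threshold_atlas(cohort.atlas, atlas_threshold)
    ref_box = reference_box_mask(cohort.grid, cohort.ref_center_mm)
    idx = tuple(mask.voxels.T)
    rows, ids = [], []
    for rec in cohort.records:
        vol = cohort.volumes[rec.id]
        cmap = cnr_map(vol, reference_stats(vol, ref_box))
        rows.append(smooth_cnr(cmap, smooth_fwhm_mm, mask).data[idx])
        ids.append(rec.id)
    return np.vstack(rows), mask, ids


def cohort_summaries(
    cohort: Cohort, atlas_threshold: float = 0.05
) -> list:
    """Regional CNR summaries for every subject (no smoothing, no QA)."""
    mask = threshold_atlas(cohort.atlas, atlas_threshold)
    ref_box = reference_box_mask(cohort.grid, cohort.ref_center_mm)
    out = []
    for rec in cohort.records:
        vol = cohort.volumes[rec.id]
        cmap = cnr_map(vol, reference_stats(vol, ref_box))
        out.append(regional_cnr(cmap, rec.id, mask, cohort.grid))
    return out


def subregional_ancovas(measures: CohortMeasures, snr_region_matched: bool = True):
    """The three subregional ANCOVAs (group effect, SNR+DSC covariates)."""
    df = measures.summary_df.merge(measures.qa_df, on=["id", "group"])
    out = {}
    for region in SUBREGIONS:
        snr_col = f"snr_{region}" if snr_region_matched else "snr_whole"
        res, posthoc = ancova_group(
            df[region], df["group"], df[[snr_col, "dsc"]]
        )
        out[region] = {"test": res, "posthoc": posthoc}
    return out


def group_design(records: list[SubjectRecord], groups: tuple[str, str]):
    """Two-group design (intercept + indicator) and one-sided contrasts."""
    sel = [r for r in records if r.group in groups]
    ids = [r.id for r in sel]
    ind = np.array([1.0 if r.group == groups[1] else 0.0 for r in sel])
    X = np.column_stack([np.ones(len(sel)), ind])
    contrasts = {
        f"{groups[0]}>{groups[1]}": np.array([0.0, -1.0]),
        f"{groups[1]}>{groups[0]}": np.array([0.0, 1.0]),
    }
    return ids, X, contrasts


def score_design(records: list[SubjectRecord], score: str,
                 covariates: tuple[str, ...] = ()):
    """Patient-group score regression design with optional covariates."""
    sel = []
    for r in records:
        if r.group not in ("PD", "PSP"):
            continue
        vals = [r.score(score)] + [
            getattr(r, c if c != "LEDD" else "ledd", np.nan) if c != "age" else r.age
            for c in covariates
        ]
        if any(np.isnan(v) for v in vals):
            continue
        sel.append(r)
    ids = [r.id for r in sel]
    cols = [np.ones(len(sel)), np.array([r.score(score) for r in sel])]
    for c in covariates:
        cols.append(np.array([r.age if c == "age" else r.ledd for r in sel]))
    X = np.column_stack(cols)
    c_pos = np.zeros(X.shape[1]); c_pos[1] = 1.0
    contrasts = {f"{score}+": c_pos, f"{score}-": -c_pos}
    return ids, X, contrasts


def _manifest(config: PipelineConfig, timings: dict[str, float]) -> dict:
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return {
        "lcquant_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {k: round(v, 3) for k, v in timings.items()},
    }


def run_pipeline(config: PipelineConfig, write_volumes: bool = False) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    t0 = time.perf_counter()
    config.simulation.seed = config.seed
    cohort = make_cohort(config.simulation)
    if write_volumes:
        write_cohort(cohort, out / "cohort")
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    measures = extract_cohort_measures(
        cohort, config.atlas_threshold, config.smooth_fwhm_mm
    )
    measures.summary_df.to_csv(out / "summary.tsv", sep="\t", index=False)
    measures.qa_df.to_csv(out / "qa.tsv", sep="\t", index=False)
    timings["cnr"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    qa = qa_report(measures.qa_df)
    qa_tab = pd.DataFrame(
        [
            {"test": "anova_dsc", **qa["anova_dsc"]},
            {"test": "anova_pons_volume", **qa["anova_pons_volume"]},
            *(
                {"test": f"snr_{k}", **v}
                for k, v in qa.get("snr_anova", {}).items()
            ),
        ]
    )
    qa_tab.to_csv(out / "qa_report.tsv", sep="\t", index=False)
    results["qa"] = qa
    timings["qa"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ancovas = subregional_ancovas(measures)
    bonf = bonferroni_threshold(config.alpha, config.n_subregion_models)
    stats_rows = []
    for region, res in ancovas.items():
        t = res["test"]
        stats_rows.append(
            {"region": region, "F": t.value, "df1": t.df[0], "df2": t.df[1],
             "p": t.p, "significant": t.p < bonf}
        )
    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out / "stats_report.tsv", sep="\t", index=False)
    results["ancova"] = ancovas
    timings["group_stats"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lmm_rows = []
    lmm_bonf = bonferroni_threshold(config.alpha, config.n_models)
    results["lmm"] = {}
    for score in config.lmm_scores:
        data = stack_cnr(measures.summaries, measures.records, score)
        fit = fit_clinical_lmm(data)
        results["lmm"][score] = fit
        for term, st in fit.terms.items():
            lmm_rows.append(
                {"score": score, "term": term, "beta": st.beta, "se": st.se,
                 "F": st.F, "df1": st.df_num, "df2": st.df_den, "p": st.p,
                 "significant": st.p < lmm_bonf}
            )
        for g, st in fit.slopes.items():
            lmm_rows.append(
                {"score": score, "term": f"slope[{g}]", "beta": st.beta,
                 "se": st.se, "F": st.F, "df1": st.df_num, "df2": st.df_den,
                 "p": st.p, "significant": ""}
            )
    pd.DataFrame(lmm_rows).to_csv(out / "lmm_report.tsv", sep="\t", index=False)
    timings["lmm"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    id_pos = {sid: k for k, sid in enumerate(measures.subject_order)}
    cluster_frames = []
    for pair in (("HC", "PD"), ("HC", "PSP")):
        ids, X, contrasts = group_design(measures.records, pair)
        Y = measures.Y[[id_pos[i] for i in ids]]
        res = permutation_fwe(Y, X, contrasts, measures.mask, measures.grid,
                              config.tfce)
        cluster_frames.append(res.clusters)
        results[f"voxelwise_{pair[0]}_{pair[1]}"] = res
    clusters = pd.concat(cluster_frames, ignore_index=True)
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    timings["voxelwise"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    asym_records = build_asymmetry_records(
        measures.summaries, measures.records, measures.subregion_sides, "PD"
    )
    asym_rows = []
    if len(asym_records) >= 4:
        reg = ai_regression(
            [a.ai_motor for a in asym_records], [a.ai_lc for a in asym_records]
        )
        asym_rows.append(
            {"analysis": "ai_regression", "stat": reg.value, "p": reg.p,
             "effect": reg.effect.get("r2")}
        )
        for region in SUBREGIONS:
            tab, test = lateralization_table(
                [a.lat_lc[region] for a in asym_records],
                [a.lat_motor for a in asym_records],
            )
            asym_rows.append(
                {"analysis": f"lateralization_{region}",
                 "stat": test.value if test else np.nan,
                 "p": test.p if test else np.nan,
                 "effect": test.effect.get("cramers_v") if test else np.nan}
            )
    asym_df = pd.DataFrame(asym_rows)
    asym_df.to_csv(out / "asymmetry_report.tsv", sep="\t", index=False)
    results["asymmetry"] = asym_df
    timings["asymmetry"] = time.perf_counter() - t0

    # report
    demo = records_to_frame(measures.records)
    demo_tab = demo.groupby("group")[["age", "education"]].agg(["mean", "std"])
    report = ["# lcquant run report", "",
              f"Seed: {config.seed}; subjects: {len(measures.records)}", "",
              "## Demographics", demo_tab.to_markdown(), "",
              "## Subregional ANCOVA (SNR+DSC covariates)",
              stats_df.to_markdown(index=False), "",
              "## QA", qa_tab.to_markdown(index=False), "",
              "## Clinical mixed-effect models",
              pd.DataFrame(lmm_rows).to_markdown(index=False), "",
              "## TFCE clusters (FWE p < {:.2f})".format(config.tfce.alpha),
              clusters.to_markdown(index=False), "",
              "## Asymmetry", asym_df.to_markdown(index=False), ""]
    (out / "report.md").write_text("\n".join(report))
    manifest = _manifest(config, timings)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    results["manifest"] = manifest
    results["clusters"] = clusters
    results["stats_df"] = stats_df
    return results
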