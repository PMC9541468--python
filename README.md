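# lcquant

Quantification of locus coeruleus (LC) integrity from neuromelanin-sensitive
magnetization-transfer (MT) MRI, for studies of parkinsonian disorders
(Parkinson's disease, progressive supranuclear palsy) and healthy ageing.
The LC is a tiny (~1 × 16 mm) bilateral brainstem nucleus whose
neuromelanin-rich noradrenergic neurons make it hyperintense on MT images;
its degeneration is an early event in PD and PSP and relates to apathy and
cognitive decline. `lcquant` implements the full analysis chain from
coregistered MT volumes to group statistics, clinical correlations and
voxelwise inference — plus a synthetic cohort generator so every stage is
testable without scanner data.

## What it computes

**Contrast-to-noise ratio.** For each voxel *v* of a coregistered MT volume,

```
CNR_v = (I_v − μ_ref) / σ_ref
```

where μ_ref and σ_ref are the mean and sample SD of the raw signal in a
4 × 4 × 4.5 mm reference box in the central pons. LC signal is extracted
with a probabilistic LC atlas thresholded at 5% (no subject-level
segmentation), summarised over the whole LC, left/right hemispheres
(midline split at template x = 0), three equidistant rostrocaudal
subregions, and per-slice profiles.

**Quality control.** Dice similarity DSC = 2|I∩S|/(|I|+|S|) between each
subject's coregistered pons mask and the template pons mask (registration
accuracy), and regional SNR = mean/SD of the raw signal (signal quality),
with group ANOVAs and a mixed subregion × group ANOVA.

**Group statistics.** Subregional ANCOVAs (group effect with SNR and DSC
as covariates of no interest, Tukey–Kramer post hocs), pooled-variance
t tests (with a summary-statistic entry point), Pearson χ² and Cramer's V,
Bonferroni/Holm adjustments, linear/quadratic regressions.

**Clinical mixed-effect model.** `CNR ~ score × group + LC definition +
(1 | subject)` over patients, REML-fitted with Satterthwaite denominator
degrees of freedom and per-group simple slopes.

**Voxelwise inference.** 1-mm FWHM smoothing, atlas masking, per-voxel GLM
contrasts, threshold-free cluster enhancement
(TFCE(v) = Σ_h e(h,v)^0.5 · h² · dh, dh = h_max/100, 26-connectivity) and
family-wise error control by the maximum-statistic permutation distribution
(Freedman–Lane), corrected jointly across contrasts; cluster tables with
local maxima in template mm.

**Asymmetry.** Asymmetry index AI = (right − left)/(right + left) for LC
contrast and lateralized motor scores, lateralization cross-tabulations
(χ² + Cramer's V) and AI-on-AI regression.

## Worked example

```python
import numpy as np
from lcquant import (SimulationConfig, make_cohort, extract_cohort_measures,
                     fit_clinical_lmm, stack_cnr)
from lcquant.pipeline import subregional_ancovas

cohort = make_cohort(SimulationConfig(seed=1))   # 24 HC / 25 PD / 14 PSP
measures = extract_cohort_measures(cohort)

print(measures.summary_df.groupby("group")[["rostral", "central", "caudal"]]
      .mean().round(2))
caudal = subregional_ancovas(measures)["caudal"]["test"]
print(f"caudal ANCOVA: F({caudal.df[0]:.0f},{caudal.df[1]:.0f}) = "
      f"{caudal.value:.2f}, p = {caudal.p:.4f}")

fit = fit_clinical_lmm(stack_cnr(measures.summaries, measures.records, "AS"))
i = fit.terms["score_x_group"]
print(f"AS x group: beta = {i.beta:.2f}, SE = {i.se:.2f}, "
      f"F(1,{i.df_den:.0f}) = {i.F:.2f}, p = {i.p:.3f}")
```

Output:

```
       rostral  central  caudal
group
HC        2.80     2.82    2.82
PD        2.51     2.40    2.21
PSP       2.29     1.96    1.36
caudal ANCOVA: F(2,58) = 15.50, p = 0.0000
AS x group: beta = 0.19, SE = 0.28, F(1,35) = 0.45, p = 0.509
```

Both disease groups lose contrast with a caudal-predominant gradient
(PSP caudal 1.36 vs 2.82 in controls), the covariate-adjusted caudal
group effect is strongly significant, and this particular seed's
apathy-by-group interaction is a typical draw from the moderate-coupling
regime built into the generator defaults (single cohorts are not
guaranteed to show it).

The same stages are available from the shell:

```
lcquant simulate --seed 1 --out cohort/
lcquant cnr --mt cohort/sub-001_mt.nii.gz --atlas cohort/lc_atlas.nii.gz \
        --refbox-center 0 -38.5 -25 --out cnr_out/
lcquant run-all --seed 1 --n-perm 500 --out run/
```

`run-all` writes `summary.tsv`, `qa_report.tsv`, `stats_report.tsv`,
`lmm_report.tsv`, `clusters.tsv`, `asymmetry_report.tsv`, a Markdown
report and a run manifest (seed, config hash, stage timings).

## Documentation

See `docs/methods.md` for the statistical model, generator assumptions,
numerical choices and known limitations.
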