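# Methods

## Analysis model

### CNR against a pontine reference

LC integrity is quantified as a contrast-to-noise ratio per voxel,
`CNR_v = (I_v − μ_ref) / σ_ref`, with μ_ref and σ_ref the mean and
*sample* SD (ddof = 1 throughout the package) of the raw MT signal in a
4 × 4 × 4.5 mm axis-aligned box in the central pons. The box is defined
in world mm and voxelized half-open, so on the 0.5 mm analysis grid it
always contains 8 × 8 × 9 = 576 voxels. The pons is used as the noise
reference because it is adjacent to the LC and — by construction in the
synthetic cohort, and by empirical check in real cohorts — its MT signal
does not differ between groups. A configuration flag of the generator
(`reference_shift`) can inject a group-dependent reference shift to test
robustness against violations of this assumption.

CNR is invariant to global affine intensity transforms `a·I + b` (a > 0)
of a volume, because the reference statistics transform identically.

### Atlas-based extraction

No subject-level LC segmentation is performed: intensity-based or manual
segmentation is biased in clinical cohorts where signal loss degrades
segmentation itself. Instead a probabilistic LC atlas in template space
is thresholded at probability ≥ 0.05 (inclusive; the "5% atlas" is a
named level, and inclusivity must be fixed for reproducible voxel
counts). The thresholded mask is decomposed into:

* hemispheres — left = world x < 0, right = x ≥ 0, ties (x exactly 0)
  to the right;
* three rostrocaudal subregions — the occupied z-slices (n of them) are
  partitioned at `round(n/3)` and `round(2n/3)` (round half up), counted
  from the caudal end, so 13 slices split 4/5/4. "Equidistant" is
  otherwise underspecified for n not divisible by 3; this rule is
  exhaustive, disjoint, and puts the remainder in the central block;
* per-slice cross-sections, reported rostral (high z) → caudal.

Subregional and hemisphere means are unweighted arithmetic means over
binary-mask voxels (not atlas-probability-weighted); the whole-LC mean
therefore decomposes exactly as the voxel-count-weighted mean of any
partition.

### Quality-control indices

Registration accuracy: Dice coefficient between each subject's
coregistered pons mask and the one template pons mask shared by all
subjects. Signal quality: SNR = mean/sample-SD of the raw MT signal per
subregion and for the whole LC. The QA report runs one-way ANOVAs on DSC
and pons volume and a mixed ANOVA on SNR (within factor subregion,
between factor group). The within-factor F is reported
sphericity-assumed by default; a Greenhouse–Geisser-corrected p value is
computed from the epsilon estimate and can be promoted to the headline p
by flag. With only three within levels the two rarely disagree.

### Group statistics

Subregional group differences use ANCOVA: regional CNR ~ group + SNR +
DSC, with a type-II F for group (no interaction modelled; the covariates
are of no interest). The SNR covariate is region-matched by default
(rostral model uses rostral SNR), switchable to whole-LC SNR. Post hocs
are Tukey–Kramer comparisons of the covariate-adjusted group means, with
studentized-range p values from `scipy.stats.studentized_range`; the
Tukey–Kramer SE form handles unequal group sizes. Three subregional
models are Bonferroni-corrected (α/3 ≈ 0.017).

Demographic comparisons use pooled-variance t tests and Pearson χ²
without continuity correction. Both conventions were fixed by
recomputing a published demographics table from its printed summaries:
pooled (not Welch) t and uncorrected (not Yates) χ² reproduce the
printed p values. Welch remains available behind a flag. Effect size for
categorical association is Cramer's V = sqrt(χ²/(n·min(r−1, c−1))).

### Clinical mixed-effect model

The clinical correlation model stacks three outcomes per patient (mean
CNR of the whole, left and right LC, capturing lateralized effects) and
fits

    CNR ~ score × group + lc_definition + (1 | subject)

over the two patient groups only (the hypothesis concerns patients; HC
are excluded). Score and outcome are z-scored over the modelled sample
by default so coefficients are unitless standardized slopes; raw-scale
fits are available by flag. Group uses treatment coding with PD as
reference; the reported "score" term is the marginal slope (average of
the two group slopes), the interaction is the slope difference, and
per-group simple slopes are always reported.

The fit maximises the restricted likelihood. For a single random
intercept the covariance is block-diagonal with `V_i = σ²_e I + σ²_b J`,
so the REML criterion is evaluated in closed form per block and profiled
down to a 1-D optimisation over the variance ratio. Denominator degrees
of freedom use the Satterthwaite approximation:
`ν = 2·f²/Var(f)` with `f = Var(c'β̂)`, the gradient of f taken
numerically over (σ²_b, σ²_e) and Var(θ̂) from the numeric REML
information matrix. With three balanced repeats per subject this yields
ν = n_subjects − 4 for between-subject contrasts (e.g. 35 at n = 39),
matching conventional F(1, 35)/t(35)-style reporting. If the
random-intercept variance collapses to ~0 the model falls back to OLS
with cluster-robust (by subject) standard errors and flags the fallback;
in that regime the fixed-effect estimates equal stacked OLS exactly.

### Voxelwise inference

Subject CNR maps are smoothed with a 1-mm FWHM Gaussian
(σ = FWHM/2.3548 converted to voxels, reflective boundary padding, which
conserves total intensity), then masked with the thresholded atlas —
smoothing before masking, masking before statistics. Per voxel, an OLS
GLM gives `t = c'β̂ / sqrt(σ̂² c'(X'X)⁻¹c)` with df = n − rank(X).

TFCE integrates cluster support over thresholds:

    TFCE(v) = Σ_{h = dh, 2dh, …, h_v} e(h, v)^E · h^H · dh

with e(h, v) the voxel count of the connected (≥ h) cluster containing
v, E = 0.5, H = 2, dh = h_max/100 and 26-connectivity — the established
volumetric defaults of the method. Only positive statistics are
enhanced; negative-direction effects are tested as separate one-sided
contrasts on the negated map. The implementation enumerates the
thresholds explicitly over an in-mask adjacency graph (numba-compiled
BFS per threshold), and is verified in the test suite against an
independent brute-force threshold-loop oracle using dense flood-fill
labelling, to 1e-9.

Family-wise error control uses the permutation distribution of the
maximum TFCE value over all in-mask voxels *and all contrasts*, so
inference is corrected across contrasts as well as space (correction
across contrasts can only be conservative for any single contrast).
Permutations follow the Freedman–Lane scheme: the design is
reparametrized so the tested quantity is a single column (an invertible
change of basis whose inverse has the contrast as its first row), data
are residualized against the nuisance columns, residuals are
row-permuted, the nuisance fit is added back, and the full-model t is
recomputed. With no nuisance regressors beyond the intercept this
reduces to simple label exchange. Empirical p values include the
unpermuted statistic: `p(v) = (1 + #{perm max ≥ TFCE_obs(v)})/(n_perm + 1)`,
so the smallest attainable p is 1/(n_perm + 1). When n! ≤ n_perm the
permutation group is enumerated exhaustively (with a warning) instead of
sampled. Group comparisons between distinct subjects are two-sample GLM
contrasts; a paired scheme is not applicable across different
participants.

Significant clusters (FWE p < α) are connected components at the
configured connectivity, reported with voxel count, volume
(count × voxel volume, 0.125 mm³ on the 0.5 mm grid), the peak-t local
maximum in template mm, and the minimum FWE p. One peak per component is
reported; sub-peak decomposition is not attempted.

### Asymmetry analyses

AI = (right − left)/(right + left) for whole-LC CNR and for lateralized
motor scores (pre-computed left/right UPDRS-III sums; item-level parsing
is out of scope). Categorical lateralization takes the side of *lower*
contrast per subregion (atrophy side) and the side of *higher* motor
score; ties are assigned "right" with a warning (tie handling is
otherwise unspecified, and ties have measure zero for continuous CNR).
Cross-tabulations are tested by Pearson χ² with Cramer's V; AI–AI
association by OLS regression of motor AI on LC AI.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not MR physics. On a 0.5 mm grid (default 60 × 60 × 48, world origin
placed so the midline is x = 0 and the pons centre sits at
(0, −38.5, −25) mm):

* **LC geometry** — two parallel tubes, 16 mm long, mirror-symmetric at
  x = ±4.25 mm, with a probabilistic atlas `0.95·exp(−d²/2σ²)`
  (σ = 0.4 mm radial) that peaks ≥ 0.9 on the axes and decays below
  threshold within ~2 voxels.
* **Signal model** — homogeneous pontine background (100 a.u.); LC
  support voxels (atlas ≥ 5%) multiplied by `gain·(1 − attenuation)`
  with gain 1.15, so baseline LC CNR ≈ 3 at the default noise; additive
  i.i.d. Gaussian noise (SD 5 a.u.). Gaussian rather than Rician noise:
  the analysis operates far from the noise floor, where the Rician
  distribution is indistinguishable from Gaussian; the config leaves a
  slot for alternatives.
* **Degeneration** — per-group mean attenuation per subregion, ordered
  caudal ≥ central ≥ rostral for disease groups (HC 0/0/0,
  PD 0.005/0.015/0.03, PSP 0.01/0.03/0.06), plus a per-subject severity
  deviation (SD 0.05, shared across subregions, clipped to [0, 1]).
  These defaults place the caudal PSP−HC standardized difference near
  1.1 and the PD−HC difference near 0.55 — a caudal-predominant,
  PSP-worse gradient of the magnitude implied by the group tests the
  pipeline is meant to detect.
* **Registration jitter** — individual pons masks are re-voxelized
  ellipsoids displaced by N(0, 0.9 mm) per axis, yielding DSC ≈ 0.88
  with spread comparable to reported registration accuracy (≈ 0.875 ±
  0.02, range 0.74–0.89). The rostrocaudal axis is grid z with rostral =
  higher z, matching the slice-profile convention.
* **Clinical scores** — drawn per group from published-table means/SDs
  (e.g. MoCA 28.6/28.0/24.0 for HC/PD/PSP); scales not administered in a
  group (RBDSQ, UPDRS-III in HC; PSPRS outside PSP) are missing.
  Couplings are standardized: score_z = slope·severity + noise, with
  noise SD = sqrt(1 − slope²) by default so the slope is the
  score–severity correlation. Default couplings: apathy +0.5, MoCA −0.4,
  ACE-R −0.3 (positive = worse score with more degeneration, given each
  scale's direction). Lateralized motor scores couple ipsilaterally to
  the LC attenuation asymmetry (correlation 0.5 by default), emulating
  same-side motor involvement.
* **Reproducibility** — every subject draws from
  `SeedSequence(master_seed, (counter, stream))`; stream 0 carries
  severity/scores/jitter, stream 1 the volume noise, so a single subject
  volume can be regenerated in isolation and cohorts are reproducible
  subject by subject.

What the generator does *not* emulate: bias fields, motion, partial
volume at the LC boundary (LC support is binary), spatially correlated
noise, registration error beyond rigid pons-mask jitter, and any
nonlinearity in score–degeneration relationships. Passing tests
therefore demonstrate that the estimators and inference procedures are
correct and calibrated under the assumed data-generating model — not
that the pipeline is robust to every artifact of real 7 T data.

## Numerical choices

* Sample SD (ddof = 1) everywhere a SD enters a formula.
* Atlas threshold inclusive (≥ level); hemisphere tie at x = 0 → right;
  subregion remainder → central block (round half up).
* ANCOVA collinearity guard: condition number of the scaled design
  > 1e8 raises.
* REML profile optimisation over log variance ratio on [−12, 8], with an
  explicit boundary check at ratio 0; singular fits (σ²_b ≤ 1e-8·σ²_e)
  trigger the OLS fallback. Satterthwaite derivatives use central
  differences with relative step 1e-4, and the df is clamped to
  (1, N − p].
* TFCE thresholds are k·(h_max/100), k = 1…100, suprathreshold is ≥ h;
  maps that are everywhere ≤ 0 enhance to zero.
* Permutation p values always include the identity permutation in the
  denominator (+1 convention).
* Degenerate inputs fail loudly: zero reference SD, empty masks after
  thresholding, < 3 occupied slices, zero-variance scores, zero AI
  denominators all raise with specific messages rather than propagating
  NaNs. Exactly-null ANOVA inputs (zero between-group sum of squares)
  report F = 0, p = 1 instead of 0/0.

## Simulation study sizes

The packaged simulation studies (test suite and acceptance script) use a
reduced phantom — 24 × 24 × 20 grid, 8 mm tubes, ~384 LC voxels — with
the same signal model as the full-size default. Calibration of the
permutation FWE uses 500 replicates of n = 20 + 20 null cohorts at 500
permutations; sensitivity uses 50 replicates with a caudal-only deficit
of 1.5 between-subject SDs; clinical-model recovery uses 100 replicates
at the study's n = 25/14 plus 200 null replicates. These sizes give
binomial/KS resolution appropriate to the thresholds being checked while
keeping the full suite runnable on a laptop core.

## Known limitations

* The TFCE step count is fixed (dh = h_max/100) rather than adaptive;
  extremely spiky maps would integrate slightly differently with a finer
  step.
* Satterthwaite df is approximate away from balanced designs, and the
  OLS fallback's cluster-robust errors are asymptotic in the number of
  subjects.
* The mixed ANOVA for SNR assumes a balanced subregion factor (every
  subject contributes all three subregions).
* `corrcon`-style correction across contrasts is implemented for
  contrasts sharing one design matrix; joint correction across different
  designs is not supported.
* The generator's binary LC support means no partial-volume gradient at
  the LC edge; atlas-weighted extraction would differ slightly on real
  data (binary-mask means are used, as flagged in the extraction docs).
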