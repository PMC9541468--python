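"""Synthetic MT cohort generator.

Emulates the statistical structure the LC analysis assumes, so every
downstream stage is testable without access to scanner data:

* bilateral tube-shaped hyperintense LC (two parallel tubes ~16 mm long,
  ~1.5 mm diameter) near the midline of a homogeneous pontine background;
* a probabilistic LC atlas peaked (>= 0.9) on the tube axes and decaying
  to zero within ~2 voxels, mirror-symmetric about the midplane;
* group-dependent LC signal attenuation with a caudal-predominant
  gradient (caudal >= central >= rostral for disease groups);
* additive Gaussian noise and registration jitter on the individual pons
  masks (which drives Dice variability);
* clinical scores linearly coupled to each subject's true LC attenuation
  through a latent severity variable.

Geometry is in template-like world coordinates: the midline is x = 0,
rostral is higher z.  Per-subject randomness is derived from the master
seed and the subject counter, so cohorts are reproducible subject by
subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GROUPS, RegionMask, SubjectRecord, VolumeGrid, write_subject_table, write_volume
from .cnr import reference_box_mask, split_subregions, threshold_atlas

__all__ = [
    "CouplingSpec",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "small_config",
    "make_grid",
    "make_atlas",
    "make_pons_mask",
    "make_subject_volume",
    "make_cohort",
    "write_cohort",
]

SUBREGIONS = ("rostral", "central", "caudal")

# Group-level score distributions used as generator defaults
# (mean, SD) per group; None = scale not administered in that group.
_SCORE_DEFAULTS: dict[str, dict[str, tuple[float, float] | None]] = {
    "MMSE": {"HC": (29.75, 0.53), "PD": (29.52, 0.65), "PSP": (28.5, 1.74)},
    "MoCA": {"HC": (28.58, 1.44), "PD": (27.96, 1.88), "PSP": (24.0, 3.94)},
    "ACE-R": {"HC": (97.71, 3.25), "PD": (95.40, 3.61), "PSP": (87.21, 7.17)},
    "AS": {"HC": (10.38, 5.25), "PD": (12.44, 5.43), "PSP": (20.0, 9.49)},
    "BIS": {"HC": (55.71, 9.56), "PD": (58.18, 10.31), "PSP": (63.86, 12.44)},
    "HADS-D": {"HC": (2.83, 2.84), "PD": (4.24, 2.73), "PSP": (7.43, 4.27)},
    "HADS-A": {"HC": (4.29, 3.53), "PD": (5.04, 3.16), "PSP": (6.57, 3.2)},
    "RBDSQ": {"HC": None, "PD": (5.48, 3.65), "PSP": (3.07, 1.82)},
    "UPDRS-III": {"HC": None, "PD": (28.36, 11.98), "PSP": (33.07, 6.96)},
    "PSPRS": {"HC": None, "PD": None, "PSP": (30.79, 9.11)},
}
_AGE_DEFAULTS = {"HC": (65.5, 5.5), "PD": (67.4, 7.4), "PSP": (69.7, 7.7)}
_EDU_DEFAULTS = {"HC": (14.8, 3.1), "PD": (14.1, 2.3), "PSP": (12.3, 2.8)}
_LEDD_DEFAULTS = {"HC": None, "PD": (644.3, 499.36), "PSP": (323.57, 389.4)}
_MALE_FRACTION = {"HC": 13 / 24, "PD": 18 / 25, "PSP": 8 / 14}


@dataclass
class CouplingSpec:
    """Linear coupling between a clinical score and LC attenuation.

    ``slope`` is on the standardized scale: the correlation between the
    score and the subject's latent degeneration severity (equal to the
    standardized true mean attenuation when no clipping occurs).  It may
    be a single value or a per-group map.  ``noise_sd`` is the residual
    score SD on the standardized scale; ``None`` picks sqrt(1 - slope^2)
    so the generated score keeps unit variance before rescaling.
    """

    slope: float | dict[str, float] = 0.0
    noise_sd: float | None = None

    def slope_for(self, group: str) -> float:
        if isinstance(self.slope, dict):
            return float(self.slope.get(group, 0.0))
        return float(self.slope)

    def noise_for(self, group: str) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        s = self.slope_for(group)
        return math.sqrt(max(0.0, 1.0 - s * s))


@dataclass
class SimulationConfig:
    """Generator configuration; defaults emulate the study conditions."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 24, "PD": 25, "PSP": 14}
    )
    grid_shape: tuple[int, int, int] = (60, 60, 48)
    resolution: float = 0.5  # mm per voxel edge
    # LC geometry (world mm)
    tube_length_mm: float = 16.0
    tube_offset_mm: float = 4.25  # |x| of each tube axis
    tube_y_mm: float = 5.25  # posterior offset from pons centre
    atlas_sigma_mm: float = 0.4  # radial decay of atlas probability
    atlas_peak: float = 0.95
    # signal model
    background: float = 100.0  # homogeneous pontine intensity (a.u.)
    baseline_lc_gain: float = 1.15
    degeneration: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # (rostral, central, caudal) mean attenuation fractions;
            # caudal-predominant, PSP > PD, scaled so the caudal PSP-HC
            # standardized difference is ~1.1 at the default att. SD
            "HC": (0.0, 0.0, 0.0),
            "PD": (0.005, 0.015, 0.03),
            "PSP": (0.01, 0.03, 0.06),
        }
    )
    attenuation_sd: float = 0.05  # between-subject SD, added to all subregions
    asymmetry_sd: float = 0.04  # SD of right-minus-left attenuation difference
    asym_regions: tuple[str, ...] = SUBREGIONS  # where the asymmetry applies
    noise_sd: float = 5.0  # additive Gaussian noise (a.u.)
    jitter_mm: float = 0.9  # registration jitter SD for individual pons masks
    reference_shift: dict[str, float] = field(default_factory=dict)
    # clinical couplings (standardized slopes vs latent severity)
    coupling: dict[str, CouplingSpec] = field(
        default_factory=lambda: {
            "AS": CouplingSpec(slope=0.5),
            "MoCA": CouplingSpec(slope=-0.4),
            "ACE-R": CouplingSpec(slope=-0.3),
        }
    )
    motor_ipsi_coupling: float = 0.5  # corr(motor AI, LC attenuation asymmetry)
    motor_asym_scale: float = 4.0  # UPDRS points per SD of lateralization
    # pons geometry
    pons_semiaxes_mm: tuple[float, float, float] = (11.0, 9.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, att in self.degeneration.items():
            if any(not 0 <= a <= 1 for a in att):
                raise ValueError(f"attenuation fractions for {g} must lie in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        half_len = self.tube_length_mm / 2
        half_extent = self.grid_shape[2] * self.resolution / 2
        if half_len >= half_extent:
            raise ValueError("LC tubes do not fit inside the grid (z extent)")
        if self.tube_offset_mm >= self.grid_shape[0] * self.resolution / 2:
            raise ValueError("LC tubes do not fit inside the grid (x extent)")


def small_config(**overrides) -> SimulationConfig:
    """A reduced phantom for fast simulation studies.

    Same signal model as the default configuration on a 24 x 24 x 20
    grid with ~8 mm tubes; used by calibration/sensitivity experiments.
    """
    cfg = SimulationConfig(
        grid_shape=(24, 24, 20),
        tube_length_mm=8.0,
        tube_offset_mm=2.25,
        tube_y_mm=2.25,
        pons_semiaxes_mm=(5.0, 4.5, 4.5),
    )
    return replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Per-subject generative truth, for recovery testing."""

    table: pd.DataFrame  # id, group, severity, asymmetry, att_* columns
    atlas_level: float = 0.05

    def attenuation(self, subject_id: str, region: str) -> float:
        row = self.table.loc[self.table["id"] == subject_id]
        return float(row[f"att_{region}"].iloc[0])


@dataclass
class Cohort:
    """In-memory synthetic cohort bundle."""

    config: SimulationConfig
    grid: VolumeGrid  # template grid (zeros)
    atlas: RegionMask  # probabilistic
    pons_template: RegionMask
    pons_individual: dict[str, RegionMask]
    ref_center_mm: tuple[float, float, float]
    volumes: dict[str, VolumeGrid]
    records: list[SubjectRecord]
    truth: GroundTruth


def make_grid(config: SimulationConfig) -> VolumeGrid:
    """Template grid: 0.5 mm RAS affine with midline at x = 0.

    World coordinates centre the grid at (0, -38.5, -25) so cluster
    tables land in a pons-like neighbourhood of template space.
    """
    nx, ny, nz = config.grid_shape
    r = config.resolution
    affine = np.diag([r, r, r, 1.0])
    affine[:3, 3] = [
        -r * (nx - 1) / 2,
        -38.5 - r * (ny - 1) / 2,
        -25.0 - r * (nz - 1) / 2,
    ]
    return VolumeGrid(np.zeros(config.grid_shape), affine)


def _world_coords(grid: VolumeGrid):
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    A = grid.affine
    x = A[0, 0] * ii + A[0, 3]
    y = A[1, 1] * jj + A[1, 3]
    z = A[2, 2] * kk + A[2, 3]
    return x, y, z


def _pons_center(config: SimulationConfig) -> tuple[float, float, float]:
    return (0.0, -38.5, -25.0)


def make_atlas(config: SimulationConfig) -> RegionMask:
    """Probabilistic LC atlas: two mirror-symmetric tubes.

    Probability is ``atlas_peak * exp(-d^2 / (2 sigma^2))`` with d the
    radial distance (mm) from the nearest tube axis, zeroed below 0.01.
    """
    grid = make_grid(config)
    x, y, z = _world_coords(grid)
    cx, cy, cz = _pons_center(config)
    y0 = cy + config.tube_y_mm
    half = config.tube_length_mm / 2
    prob = np.zeros(grid.shape)
    in_z = (z >= cz - half + 1e-9) & (z <= cz + half - 1e-9)
    for sign in (-1.0, 1.0):
        d2 = (x - sign * config.tube_offset_mm) ** 2 + (y - y0) ** 2
        p = config.atlas_peak * np.exp(-d2 / (2 * config.atlas_sigma_mm**2))
        prob = np.maximum(prob, np.where(in_z, p, 0.0))
    prob[prob < 0.01] = 0.0
    if not (prob > 0).any():
        raise ValueError("atlas geometry produced an empty mask")
    return RegionMask.from_array(prob, "probabilistic")


def make_pons_mask(
    config: SimulationConfig, center_shift_mm=(0.0, 0.0, 0.0)
) -> RegionMask:
    """Ellipsoidal pons mask, optionally shifted (registration jitter)."""
    grid = make_grid(config)
    x, y, z = _world_coords(grid)
    c = np.asarray(_pons_center(config)) + np.asarray(center_shift_mm)
    a, b, cc = config.pons_semiaxes_mm
    inside = (
        ((x - c[0]) / a) ** 2 + ((y - c[1]) / b) ** 2 + ((z - c[2]) / cc) ** 2
    ) <= 1.0
    return RegionMask.from_array(inside.astype(float), "binary")


def _subject_rng(
    config: SimulationConfig, counter: int, stream: int = 0
) -> np.random.Generator:
    # per-subject stream: master seed + subject counter (+ substream so the
    # volume noise never reuses the severity/score draws)
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(counter, stream))
    )


def _subregion_side_masks(config: SimulationConfig, atlas: RegionMask):
    """Binary LC support split into subregion x hemisphere cells."""
    grid = make_grid(config)
    support = threshold_atlas(atlas, 0.05)
    rostral, central, caudal = split_subregions(support)
    out = {}
    for name, m in zip(SUBREGIONS, (rostral, central, caudal)):
        x_mm = (grid.affine @ np.hstack([m.voxels, np.ones((len(m), 1))]).T)[0]
        out[(name, "left")] = m.voxels[x_mm < 0]
        out[(name, "right")] = m.voxels[x_mm >= 0]
    return support, out


def _subject_attenuations(
    config: SimulationConfig, group: str, severity: float, asym: float
) -> dict[tuple[str, str], float]:
    """Attenuation per (subregion, side), clipped to [0, 1]."""
    base = dict(zip(SUBREGIONS, config.degeneration[group]))
    out = {}
    for region in SUBREGIONS:
        a = base[region] + config.attenuation_sd * severity
        d = asym if region in config.asym_regions else 0.0
        # asym = right minus left attenuation difference
        out[(region, "left")] = float(np.clip(a - d / 2, 0.0, 1.0))
        out[(region, "right")] = float(np.clip(a + d / 2, 0.0, 1.0))
    return out


def make_subject_volume(
    config: SimulationConfig,
    group: str,
    subject_seed: int,
    severity: float | None = None,
    asym: float | None = None,
    atlas: RegionMask | None = None,
    cells: dict | None = None,
) -> tuple[VolumeGrid, dict]:
    """One MT-like volume plus its generative truth.

    Homogeneous background; LC support voxels (atlas >= 5%) multiplied by
    ``baseline_lc_gain * (1 - attenuation)`` per subregion/side; i.i.d.
    Gaussian noise added last.  Deterministic given the seeds.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = _subject_rng(config, subject_seed, 0)
    if severity is None:
        severity = float(rng.standard_normal())
    if asym is None:
        asym = float(config.asymmetry_sd * rng.standard_normal())
    noise_rng = _subject_rng(config, subject_seed, 1)
    if cells is None:
        atlas = atlas if atlas is not None else make_atlas(config)
        _, cells = _subregion_side_masks(config, atlas)
    att = _subject_attenuations(config, group, severity, asym)

    data = np.full(config.grid_shape, config.background, dtype=float)
    data += config.reference_shift.get(group, 0.0)
    for key, vox in cells.items():
        if len(vox):
            data[tuple(vox.T)] = (
                config.background * config.baseline_lc_gain * (1.0 - att[key])
            )
    if config.noise_sd > 0:
        data += config.noise_sd * noise_rng.standard_normal(config.grid_shape)
    truth = {
        "severity": severity,
        "asymmetry": asym,
        "attenuation": att,
    }
    return VolumeGrid(data, make_grid(config).affine), truth


def _draw_score(rng, group, name, spec: CouplingSpec, severity) -> float:
    defaults = _SCORE_DEFAULTS[name].get(group)
    if defaults is None:
        return math.nan
    mean, sd = defaults
    z = spec.slope_for(group) * severity + spec.noise_for(group) * rng.standard_normal()
    return float(mean + sd * z)


def make_cohort(config: SimulationConfig) -> Cohort:
    """Full cohort: volumes, masks, subject records and ground truth."""
    atlas = make_atlas(config)
    grid = make_grid(config)
    pons_template = make_pons_mask(config)
    ref_center = _pons_center(config)
    _, cells = _subregion_side_masks(config, atlas)

    volumes: dict[str, VolumeGrid] = {}
    pons_individual: dict[str, RegionMask] = {}
    records: list[SubjectRecord] = []
    truth_rows = []
    counter = 0
    for group in GROUPS:
        for _ in range(config.n_per_group.get(group, 0)):
            sid = f"sub-{counter + 1:03d}"
            rng = _subject_rng(config, counter)
            severity = float(rng.standard_normal())
            asym = float(config.asymmetry_sd * rng.standard_normal())
            vol, truth = make_subject_volume(
                config, group, counter, severity=severity, asym=asym, cells=cells
            )
            jitter = (
                config.jitter_mm * rng.standard_normal(3)
                if config.jitter_mm > 0
                else np.zeros(3)
            )
            pons_individual[sid] = make_pons_mask(config, jitter)
            volumes[sid] = vol

            scores: dict[str, float] = {}
            for name in _SCORE_DEFAULTS:
                spec = config.coupling.get(name, CouplingSpec())
                scores[name] = _draw_score(rng, group, name, spec, severity)
            # lateralized motor scores: ipsilateral to LC attenuation asymmetry
            if group in ("PD", "PSP") and not math.isnan(scores["UPDRS-III"]):
                total = max(scores["UPDRS-III"], 0.0)
                rho = config.motor_ipsi_coupling
                z_asym = asym / config.asymmetry_sd if config.asymmetry_sd > 0 else 0.0
                lat = rho * z_asym + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
                delta = config.motor_asym_scale * lat
                scores["UPDRS-III-right"] = max(total / 2 + delta / 2, 0.0)
                scores["UPDRS-III-left"] = max(total / 2 - delta / 2, 0.0)
            else:
                scores["UPDRS-III-right"] = math.nan
                scores["UPDRS-III-left"] = math.nan

            age = float(np.clip(rng.normal(*_AGE_DEFAULTS[group]), 50, 80))
            edu = float(max(rng.normal(*_EDU_DEFAULTS[group]), 6.0))
            sex = "M" if rng.random() < _MALE_FRACTION[group] else "F"
            ledd_spec = _LEDD_DEFAULTS[group]
            ledd = (
                float(max(rng.normal(*ledd_spec), 0.0)) if ledd_spec else math.nan
            )
            records.append(
                SubjectRecord(
                    id=sid, group=group, scores=scores, age=age, sex=sex,
                    education=edu, ledd=ledd,
                )
            )
            att = truth["attenuation"]
            row = {"id": sid, "group": group, "severity": severity, "asymmetry": asym}
            for region in SUBREGIONS:
                row[f"att_{region}"] = (att[(region, "left")] + att[(region, "right")]) / 2
                row[f"att_{region}_left"] = att[(region, "left")]
                row[f"att_{region}_right"] = att[(region, "right")]
            row["att_mean"] = np.mean([row[f"att_{r}"] for r in SUBREGIONS])
            truth_rows.append(row)
            counter += 1
    truth = GroundTruth(table=pd.DataFrame(truth_rows))
    return Cohort(
        config=config,
        grid=grid,
        atlas=atlas,
        pons_template=pons_template,
        pons_individual=pons_individual,
        ref_center_mm=ref_center,
        volumes=volumes,
        records=records,
        truth=truth,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Persist a cohort: NIfTI volumes/masks, subjects.tsv, ground_truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(
        VolumeGrid(cohort.atlas.to_array(), cohort.grid.affine), out / "lc_atlas.nii.gz"
    )
    write_volume(
        VolumeGrid(cohort.pons_template.to_array(), cohort.grid.affine),
        out / "pons_template.nii.gz",
    )
    ref_box = reference_box_mask(cohort.grid, cohort.ref_center_mm)
    write_volume(
        VolumeGrid(ref_box.to_array(), cohort.grid.affine), out / "ref_box.nii.gz"
    )
    for sid, vol in cohort.volumes.items():
        write_volume(vol, out / f"{sid}_mt.nii.gz")
        write_volume(
            VolumeGrid(cohort.pons_individual[sid].to_array(), cohort.grid.affine),
            out / f"{sid}_pons.nii.gz",
        )
    write_subject_table(cohort.records, out / "subjects.tsv")
    cohort.truth.table.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return out
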