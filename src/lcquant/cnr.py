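"""Contrast-to-noise-ratio mapping and atlas-based LC signal extraction.

The locus coeruleus (LC) is quantified without any subject-level
segmentation: a probabilistic LC atlas in template space is thresholded
at a fixed level (default 5%, inclusive) and applied to every
coregistered magnetization-transfer (MT) volume.  Per voxel,

    CNR_v = (I_v - mu_ref) / sd_ref

where mu_ref and sd_ref are the mean and sample SD of the raw signal in
a 4 x 4 x 4.5 mm pontine reference box.  Summaries are taken over the
whole LC, each hemisphere (split at template x = 0), three equidistant
rostrocaudal subregions, and per-slice cross-sections (rostral = higher
z, reported rostral -> caudal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import RegionMask, VolumeGrid, voxel_to_mm

__all__ = [
    "ReferenceStats",
    "CNRSummary",
    "SnrValue",
    "reference_box_mask",
    "reference_stats",
    "cnr_map",
    "threshold_atlas",
    "split_subregions",
    "split_hemispheres",
    "regional_cnr",
    "snr",
]

#: Reference box edge lengths in mm (x, y, z).
REF_BOX_SIZE_MM = (4.0, 4.0, 4.5)


@dataclass
class ReferenceStats:
    """Mean/SD of the raw signal in the pontine reference box."""

    mean: float
    sd: float
    n_voxels: int
    box_center_mm: tuple[float, float, float] | None = None
    box_size_mm: tuple[float, float, float] = REF_BOX_SIZE_MM

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("reference box must contain at least 2 voxels")
        if not self.sd > 0:
            raise ValueError("zero reference SD: reference box is degenerate")


@dataclass
class CNRSummary:
    """Mean CNR per LC definition for one subject."""

    subject_id: str
    values: dict[str, float]  # whole/left/right/rostral/central/caudal
    slice_profile: list[float]  # per-slice means, rostral -> caudal
    slice_z: list[int]  # grid z-index per profile entry


@dataclass
class SnrValue:
    region: str
    snr: float


def reference_box_mask(
    grid: VolumeGrid,
    center_mm,
    size_mm: tuple[float, float, float] = REF_BOX_SIZE_MM,
) -> RegionMask:
    """Axis-aligned reference box, centred at ``center_mm``.

    The box spans ``size_mm`` in world coordinates; voxels whose centres
    fall inside the half-open box are retained.  On a 0.5 mm grid the
    default 4 x 4 x 4.5 mm box contains 8 x 8 x 9 = 576 voxels.
    """
    center = np.asarray(center_mm, dtype=float)
    half = np.asarray(size_mm, dtype=float) / 2.0
    inv = np.linalg.inv(grid.affine)
    lo_v = (inv @ np.append(center - half, 1.0))[:3]
    hi_v = (inv @ np.append(center + half, 1.0))[:3]
    lo = np.minimum(lo_v, hi_v)
    hi = np.maximum(lo_v, hi_v)
    # voxel centres in [lo, hi): half-open so the count is size/resolution
    lo_i = np.maximum(np.ceil(lo - 1e-9), 0).astype(int)
    hi_i = np.minimum(np.ceil(hi - 1e-9), grid.shape).astype(int)
    if np.any(hi_i <= lo_i):
        raise ValueError("reference box lies outside the grid")
    xs, ys, zs = [np.arange(lo_i[k], hi_i[k]) for k in range(3)]
    vox = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    return RegionMask(grid.shape, vox, "binary")


def reference_stats(volume: VolumeGrid, ref_box: RegionMask) -> ReferenceStats:
    """Mean and sample SD (ddof=1) of the raw signal over the box."""
    vals = ref_box.values_from(volume)
    if len(vals) < 2:
        raise ValueError("reference box must contain at least 2 voxels")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError("zero reference SD: reference box is degenerate")
    return ReferenceStats(mean=float(np.mean(vals)), sd=sd, n_voxels=len(vals))


def cnr_map(volume: VolumeGrid, ref: ReferenceStats) -> VolumeGrid:
    """Per-voxel (I_v - mu_ref) / sd_ref on the same grid."""
    return volume.like((volume.data - ref.mean) / ref.sd)


def threshold_atlas(atlas: RegionMask, level: float = 0.05) -> RegionMask:
    """Binary mask of atlas voxels with probability >= ``level``."""
    if not 0 < level < 1:
        raise ValueError("threshold level must lie in (0, 1)")
    if atlas.kind != "probabilistic":
        raise ValueError("threshold_atlas expects a probabilistic mask")
    keep = atlas.prob >= level
    if not keep.any():
        raise ValueError(f"empty mask: no atlas voxel reaches level {level}")
    return RegionMask(atlas.shape, atlas.voxels[keep], "binary")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_subregions(mask: RegionMask) -> tuple[RegionMask, RegionMask, RegionMask]:
    """Partition the mask's occupied z-extent into three equidistant blocks.

    With n occupied slices the boundaries fall at round(n/3) and
    round(2n/3) (round half up), counted from the caudal (low-z) end;
    rostral is the highest-z block.  Returns (rostral, central, caudal).
    """
    if len(mask) == 0:
        raise ValueError("cannot split an empty mask")
    zs = np.unique(mask.voxels[:, 2])
    n = len(zs)
    if n < 3:
        raise ValueError(f"mask occupies {n} slice(s); need at least 3")
    b1 = _round_half_up(n / 3)
    b2 = _round_half_up(2 * n / 3)
    caudal_z, central_z, rostral_z = zs[:b1], zs[b1:b2], zs[b2:]
    out = []
    for zblock in (rostral_z, central_z, caudal_z):
        keep = np.isin(mask.voxels[:, 2], zblock)
        out.append(RegionMask(mask.shape, mask.voxels[keep], "binary"))
    return out[0], out[1], out[2]


def split_hemispheres(
    mask: RegionMask, grid: VolumeGrid
) -> tuple[RegionMask, RegionMask]:
    """Split at template midline: left = mm x < 0, right = x >= 0."""
    if len(mask) == 0:
        raise ValueError("cannot split an empty mask")
    homog = np.hstack([mask.voxels, np.ones((len(mask), 1))])
    x_mm = (grid.affine @ homog.T)[0]
    left = RegionMask(mask.shape, mask.voxels[x_mm < 0], "binary")
    right = RegionMask(mask.shape, mask.voxels[x_mm >= 0], "binary")
    if len(left) == 0 or len(right) == 0:
        warnings.warn("one hemisphere mask is empty", stacklevel=2)
    return left, right


def regional_cnr(
    cnr: VolumeGrid,
    subject_id: str,
    whole: RegionMask,
    grid: VolumeGrid | None = None,
) -> CNRSummary:
    """Mean CNR per LC definition plus the rostral->caudal slice profile."""
    grid = grid or cnr
    if len(whole) == 0:
        raise ValueError("empty LC mask")
    left, right = split_hemispheres(whole, grid)
    rostral, central, caudal = split_subregions(whole)
    values = {}
    for name, m in (
        ("whole", whole), ("left", left), ("right", right),
        ("rostral", rostral), ("central", central), ("caudal", caudal),
    ):
        values[name] = float(np.mean(m.values_from(cnr))) if len(m) else float("nan")
    zs = np.unique(whole.voxels[:, 2])[::-1]  # descending z: rostral first
    profile = []
    for z in zs:
        sel = whole.voxels[:, 2] == z
        profile.append(float(np.mean(cnr.data[tuple(whole.voxels[sel].T)])))
    return CNRSummary(
        subject_id=subject_id,
        values=values,
        slice_profile=profile,
        slice_z=[int(z) for z in zs],
    )


def snr(volume: VolumeGrid, mask: RegionMask, region: str = "region") -> SnrValue:
    """Mean / sample SD of the raw signal within the mask."""
    vals = mask.values_from(volume)
    if len(vals) < 2:
        raise ValueError("SNR requires at least 2 voxels")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError("zero SD in region: SNR undefined")
    return SnrValue(region=region, snr=float(np.mean(vals)) / sd)


def slice_center_mm(grid: VolumeGrid, z_index: int) -> float:
    """World z-coordinate of a grid slice centre (for profile axes)."""
    return float(voxel_to_mm(grid, (0, 0, z_index))[2])
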