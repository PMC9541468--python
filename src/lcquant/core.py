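"""Volume/mask data model, NIfTI and TSV I/O, and coordinate conventions.

Every downstream stage operates on the three containers defined here:

* :class:`VolumeGrid` — a 3D scalar image with a voxel-index → world-mm
  affine (RAS convention of the stored affine; 0-based voxel indices).
* :class:`RegionMask` — an explicit voxel set on a grid, binary or
  probabilistic.  Masks are materialised as index sets after any
  thresholding so that downstream voxel counts are unambiguous.
* :class:`SubjectRecord` — group label, clinical scores, demographic
  covariates and QA values for one participant.

Missing clinical scores stay missing (NaN) and propagate to listwise
deletion inside each statistical model; they are never imputed as zeros.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "RegionMask",
    "SubjectRecord",
    "GROUPS",
    "read_volume",
    "write_volume",
    "voxel_to_mm",
    "mm_to_voxel",
    "read_subject_table",
    "write_subject_table",
]

#: Allowed diagnostic group labels.
GROUPS = ("HC", "PD", "PSP")


@dataclass
class VolumeGrid:
    """A 3D scalar image on a regular grid with a voxel→mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("each axis must have at least one voxel")
        if self.affine.shape != (4, 4) or not np.all(np.isfinite(self.affine)):
            raise ValueError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def resolution(self) -> float:
        """Voxel edge length in mm (isotropic grids); mean scale otherwise."""
        scales = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return float(scales.mean())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same affine and new data."""
        return VolumeGrid(np.asarray(data, dtype=float), self.affine.copy())


def read_volume(path: str | Path) -> VolumeGrid:
    """Load a 3D NIfTI-1/2 volume.

    Raises on missing files, non-3D images and non-finite affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D: {path}")
    return VolumeGrid(data, np.asarray(img.affine, dtype=float))


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    """Write a grid as NIfTI-1 (float64, so round-trips are bit-exact)."""
    img = nib.Nifti1Image(grid.data.astype(np.float64), grid.affine)
    nib.save(img, str(path))


def voxel_to_mm(grid: VolumeGrid, index) -> np.ndarray:
    """Map a 0-based voxel index to world mm via the grid affine."""
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise ValueError("index must be a voxel triple")
    if np.any(idx < 0) or np.any(idx > np.array(grid.shape) - 1):
        raise IndexError(f"voxel index {tuple(index)} out of bounds {grid.shape}")
    return (grid.affine @ np.append(idx, 1.0))[:3]


def mm_to_voxel(grid: VolumeGrid, mm) -> tuple[int, int, int]:
    """Map world mm to the nearest 0-based voxel index (inverse affine)."""
    mm = np.asarray(mm, dtype=float)
    idx = (np.linalg.inv(grid.affine) @ np.append(mm, 1.0))[:3]
    idx = np.round(idx).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
        raise IndexError(f"mm coordinate {tuple(mm)} maps outside the grid")
    return int(idx[0]), int(idx[1]), int(idx[2])


@dataclass
class RegionMask:
    """An explicit voxel set on a grid.

    ``kind`` is ``"binary"`` or ``"probabilistic"``; probabilistic masks
    carry a probability per stored voxel.
    """

    shape: tuple[int, int, int]
    voxels: np.ndarray  # (n, 3) int array of voxel indices
    kind: str = "binary"
    prob: np.ndarray | None = None  # (n,) probabilities when probabilistic

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            self.voxels = self.voxels.reshape(0, 3)
        if self.voxels.shape[1] != 3:
            raise ValueError("voxels must be an (n, 3) index array")
        if self.voxels.size and (
            np.any(self.voxels < 0) or np.any(self.voxels >= np.array(self.shape))
        ):
            raise ValueError("mask voxel indices fall outside the grid")
        if self.kind not in ("binary", "probabilistic"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if self.kind == "probabilistic":
            if self.prob is None:
                raise ValueError("probabilistic mask requires per-voxel prob")
            self.prob = np.asarray(self.prob, dtype=float)
            if self.prob.shape != (len(self.voxels),):
                raise ValueError("prob must align with voxels")
            if np.any(self.prob < 0) or np.any(self.prob > 1):
                raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.voxels)

    @classmethod
    def from_array(cls, arr: np.ndarray, kind: str = "binary") -> "RegionMask":
        arr = np.asarray(arr)
        if kind == "binary":
            vox = np.argwhere(arr > 0)
            return cls(arr.shape, vox, "binary")
        vox = np.argwhere(arr > 0)
        return cls(arr.shape, vox, "probabilistic", arr[tuple(vox.T)])

    def to_array(self) -> np.ndarray:
        """Dense array: 0/1 for binary, probabilities for probabilistic."""
        out = np.zeros(self.shape, dtype=float)
        if len(self):
            idx = tuple(self.voxels.T)
            out[idx] = 1.0 if self.kind == "binary" else self.prob
        return out

    def values_from(self, grid: VolumeGrid) -> np.ndarray:
        """Extract the grid's intensities at the mask voxels."""
        if grid.shape != self.shape:
            raise ValueError("mask and volume grids differ in shape")
        return grid.data[tuple(self.voxels.T)]

    def index_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels.tolist()}


@dataclass
class SubjectRecord:
    """One participant: group, clinical scores, covariates and QA values."""

    id: str
    group: str
    scores: dict[str, float] = field(default_factory=dict)
    age: float = math.nan
    sex: str = ""
    education: float = math.nan
    ledd: float = math.nan
    qa: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group label {self.group!r} for subject {self.id!r}"
            )

    def score(self, name: str) -> float:
        return self.scores.get(name, math.nan)


_FIXED_COLUMNS = ("id", "group", "age", "sex", "education", "LEDD")


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read a TSV subject table into records.

    Required columns: ``id`` and ``group``.  Any column other than the
    fixed set (age, sex, education, LEDD) is treated as a clinical score.
    Blank cells become NaN (explicitly missing).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ("id", "group"):
        if col not in df.columns:
            raise ValueError(f"subject table must contain a {col!r} column")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    records = []
    score_cols = [c for c in df.columns if c not in _FIXED_COLUMNS]
    for i, row in df.iterrows():
        group = str(row["group"])
        if group not in GROUPS:
            raise ValueError(f"row {i} (id={row['id']!r}): unknown group {group!r}")
        scores = {}
        for c in score_cols:
            val = pd.to_numeric(row[c], errors="coerce")
            scores[c] = float(val) if pd.notna(val) else math.nan
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                group=group,
                scores=scores,
                age=float(pd.to_numeric(row.get("age"), errors="coerce"))
                if "age" in df.columns and pd.notna(row.get("age"))
                else math.nan,
                sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row.get("sex")) else "",
                education=float(pd.to_numeric(row.get("education"), errors="coerce"))
                if "education" in df.columns and pd.notna(row.get("education"))
                else math.nan,
                ledd=float(pd.to_numeric(row.get("LEDD"), errors="coerce"))
                if "LEDD" in df.columns and pd.notna(row.get("LEDD"))
                else math.nan,
            )
        )
    return records


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    """Write records to TSV with stable column order."""
    score_names: list[str] = []
    for r in records:
        for s in r.scores:
            if s not in score_names:
                score_names.append(s)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "education": r.education,
            "LEDD": r.ledd,
        }
        for s in score_names:
            row[s] = r.scores.get(s, math.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (scores and QA as columns)."""
    rows = []
    for r in records:
        row = dict(
            id=r.id, group=r.group, age=r.age, sex=r.sex,
            education=r.education, LEDD=r.ledd,
        )
        row.update(r.scores)
        row.update(r.qa)
        rows.append(row)
    return pd.DataFrame(rows)


def record_asdict(r: SubjectRecord) -> dict:
    return dataclasses.asdict(r)
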