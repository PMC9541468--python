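"""Voxelwise GLM with TFCE and permutation-based FWE inference.

Per-subject CNR maps are smoothed (1 mm FWHM Gaussian, reflective
padding), masked with the thresholded LC atlas, and fed voxel by voxel
into an ordinary-least-squares GLM.  One-sided contrasts are enhanced
with threshold-free cluster enhancement:

    TFCE(v) = sum over h = dh, 2dh, ..., h_v of e(h, v)^E * h^H * dh

with ``e(h, v)`` the voxel count of the connected suprathreshold
(value >= h) cluster containing v, ``dh = h_max / n_steps``, and the
established volumetric defaults E = 0.5, H = 2, 26-connectivity.

Family-wise error control uses the maximum-statistic permutation
distribution (Freedman-Lane residual permutation under the tested
contrast's null), with the maximum taken over all in-mask voxels AND all
contrasts, so inference is corrected across contrasts as well as space.
Empirical p values include the unpermuted statistic:
p(v) = (1 + #{perm max >= TFCE_obs(v)}) / (n_perm + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .core import RegionMask, VolumeGrid

__all__ = [
    "TfceParams",
    "TfceResult",
    "MaskGraph",
    "smooth_cnr",
    "glm_t",
    "tfce",
    "tfce_values",
    "permutation_fwe",
    "neglog10",
    "extract_clusters",
]

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


@dataclass
class TfceParams:
    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100  # dh = h_max / n_steps
    connectivity: int = 26
    n_perm: int = 10000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class ContrastMaps:
    name: str
    t_map: VolumeGrid
    tfce_map: VolumeGrid
    fwe_p_map: VolumeGrid
    neglogp_map: VolumeGrid


@dataclass
class TfceResult:
    contrasts: dict[str, ContrastMaps]
    clusters: pd.DataFrame
    null_max: np.ndarray = field(repr=False, default=None)
    params: TfceParams | None = None


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def smooth_cnr(
    volume: VolumeGrid, fwhm_mm: float = 1.0, mask: RegionMask | None = None
) -> VolumeGrid:
    """Gaussian smoothing (sigma = FWHM/2.3548 mm), then optional masking.

    Reflective boundary padding conserves total intensity before masking.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    scales = np.sqrt((volume.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / scales
    data = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="reflect")
    if mask is not None:
        out = np.zeros_like(data)
        idx = tuple(mask.voxels.T)
        out[idx] = data[idx]
        data = out
    return volume.like(data)


def glm_t(Y: np.ndarray, X: np.ndarray, contrast) -> np.ndarray:
    """Per-voxel OLS t statistics for a contrast of the design columns.

    ``Y`` is (n_subjects, n_voxels); ``X`` is (n_subjects, p);
    t = c'b / sqrt(s2 * c'(X'X)^-1 c) with df = n - rank(X).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("rank-deficient design matrix")
    if n <= rank:
        raise ValueError("need more subjects than design rank")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - rank
    s2 = (resid**2).sum(axis=0) / df
    denom = np.sqrt(s2 * float(c @ xtx_inv @ c))
    num = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / denom, 0.0)
    return t


@dataclass
class MaskGraph:
    """Precomputed in-mask adjacency (CSR) for fast TFCE."""

    voxels: np.ndarray  # (n, 3)
    nbr_idx: np.ndarray
    nbr_ptr: np.ndarray
    shape: tuple[int, int, int]

    @classmethod
    def build(cls, mask: RegionMask, connectivity: int = 26) -> "MaskGraph":
        vox = mask.voxels
        n = len(vox)
        lut = -np.ones(mask.shape, dtype=np.int64)
        lut[tuple(vox.T)] = np.arange(n)
        offs = np.argwhere(_structure(connectivity)) - 1
        offs = offs[np.any(offs != 0, axis=1)]
        nbrs = []
        ptr = np.zeros(n + 1, dtype=np.int64)
        shp = np.array(mask.shape)
        for i in range(n):
            cand = vox[i] + offs
            ok = np.all((cand >= 0) & (cand < shp), axis=1)
            ids = lut[tuple(cand[ok].T)]
            ids = ids[ids >= 0]
            nbrs.append(ids)
            ptr[i + 1] = ptr[i] + len(ids)
        nbr_idx = (
            np.concatenate(nbrs) if nbrs else np.empty(0, dtype=np.int64)
        ).astype(np.int64)
        return cls(vox, nbr_idx, ptr, mask.shape)


@njit(cache=True)
def _tfce_kernel(vals, nbr_idx, nbr_ptr, E, H, n_steps):  # pragma: no cover
    n = vals.shape[0]
    out = np.zeros(n)
    hmax = 0.0
    for i in range(n):
        if vals[i] > hmax:
            hmax = vals[i]
    if hmax <= 0.0:
        return out
    dh = hmax / n_steps
    stack = np.empty(n, np.int64)
    members = np.empty(n, np.int64)
    visited = np.empty(n, np.uint8)
    for k in range(1, n_steps + 1):
        h = dh * k
        for i in range(n):
            visited[i] = 0
        for i in range(n):
            if vals[i] >= h and visited[i] == 0:
                visited[i] = 1
                top = 0
                stack[0] = i
                nm = 0
                while top >= 0:
                    v = stack[top]
                    top -= 1
                    members[nm] = v
                    nm += 1
                    for jj in range(nbr_ptr[v], nbr_ptr[v + 1]):
                        w = nbr_idx[jj]
                        if vals[w] >= h and visited[w] == 0:
                            visited[w] = 1
                            top += 1
                            stack[top] = w
                inc = nm**E * h**H * dh
                for m in range(nm):
                    out[members[m]] += inc
    return out


def tfce_values(values: np.ndarray, graph: MaskGraph, params: TfceParams) -> np.ndarray:
    """TFCE over in-mask values (positive part; order follows the graph)."""
    vals = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("statistic map contains non-finite values in mask")
    return _tfce_kernel(
        vals, graph.nbr_idx, graph.nbr_ptr, params.E, params.H, params.n_steps
    )


def tfce(
    stat_map: VolumeGrid, mask: RegionMask, params: TfceParams | None = None
) -> VolumeGrid:
    """TFCE enhancement of a statistic map inside a mask.

    Only the positive direction is enhanced; run on the negated map for
    negative one-sided effects.
    """
    params = params or TfceParams()
    if len(mask) == 0:
        raise ValueError("empty mask")
    graph = MaskGraph.build(mask, params.connectivity)
    vals = stat_map.data[tuple(graph.voxels.T)]
    out = np.zeros(stat_map.shape)
    out[tuple(graph.voxels.T)] = tfce_values(vals, graph, params)
    return stat_map.like(out)


def _partition_design(X: np.ndarray, c: np.ndarray):
    """Reparametrize so the tested quantity is a single column.

    Returns (T, Z) with [T Z] = X B for invertible B whose inverse has
    c' as its first row; then the coefficient of T equals c'beta and the
    columns of Z span the nuisance space.
    """
    p = X.shape[1]
    c = np.asarray(c, dtype=float).reshape(-1)
    if c.shape[0] != p:
        raise ValueError("contrast length must equal design column count")
    # null-space basis of c (rows of B_inv after c')
    _, _, Vt = np.linalg.svd(c.reshape(1, -1))
    N = Vt[1:, :]  # (p-1, p), orthonormal, orthogonal to c
    B_inv = np.vstack([c, N])
    B = np.linalg.inv(B_inv)
    W = X @ B
    return W[:, :1], W[:, 1:]


def _draw_permutations(n: int, n_perm: int, rng: np.random.Generator):
    """Row permutations; exhaustive (with a warning) when n! <= n_perm."""
    if math.factorial(n) <= n_perm:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations exist for n={n}; "
            "enumerating exhaustively",
            stacklevel=3,
        )
        from itertools import permutations

        return [np.array(p) for p in permutations(range(n))]
    return [rng.permutation(n) for _ in range(n_perm)]


def permutation_fwe(
    Y: np.ndarray,
    X: np.ndarray,
    contrasts: dict[str, np.ndarray],
    mask: RegionMask,
    grid: VolumeGrid,
    params: TfceParams | None = None,
) -> TfceResult:
    """Permutation FWE inference for one-sided contrasts.

    ``Y`` is (n_subjects, n_mask_voxels) in the order of ``mask.voxels``.
    Freedman-Lane scheme: per contrast, data are residualized against
    the nuisance partition, residuals are row-permuted, the nuisance fit
    is added back and the full-model t and TFCE recomputed.  The null
    distribution is the per-permutation maximum TFCE over voxels and
    over all contrasts (correction across contrasts).
    """
    params = params or TfceParams()
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if len(mask) != Y.shape[1]:
        raise ValueError("Y columns must match mask voxels")
    graph = MaskGraph.build(mask, params.connectivity)
    rng = np.random.default_rng(params.seed)
    perms = _draw_permutations(n, params.n_perm, rng)
    n_perm = len(perms)

    prep = {}
    for name, c in contrasts.items():
        T, Z = _partition_design(X, np.asarray(c, dtype=float))
        W = np.hstack([T, Z])
        wtw_inv = np.linalg.inv(W.T @ W)
        M = wtw_inv @ W.T  # coefficient estimator
        v00 = wtw_inv[0, 0]
        df = n - np.linalg.matrix_rank(W)
        Zg = Z @ np.linalg.pinv(Z) @ Y  # nuisance fit
        R = Y - Zg  # residualized data
        t_obs = glm_t(Y, X, c)
        tfce_obs = tfce_values(t_obs, graph, params)
        prep[name] = dict(
            W=W, M=M, v00=v00, df=df, Zg=Zg, R=R, t_obs=t_obs, tfce_obs=tfce_obs
        )

    null_max = np.zeros(n_perm)
    for j, perm in enumerate(perms):
        m = 0.0
        for name, pr in prep.items():
            Yp = pr["R"][perm] + pr["Zg"]
            beta = pr["M"] @ Yp
            fitted = pr["W"] @ beta
            rss = ((Yp - fitted) ** 2).sum(axis=0)
            s2 = rss / pr["df"]
            denom = np.sqrt(s2 * pr["v00"])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(denom > 0, beta[0] / denom, 0.0)
            tf = tfce_values(t, graph, params)
            if tf.size:
                m = max(m, float(tf.max()))
        null_max[j] = m

    idx = tuple(graph.voxels.T)
    contrast_maps: dict[str, ContrastMaps] = {}
    cluster_frames = []
    for name, pr in prep.items():
        exceed = (null_max[:, None] >= pr["tfce_obs"][None, :]).sum(axis=0)
        pvals = (1.0 + exceed) / (n_perm + 1.0)
        t_map = np.zeros(grid.shape)
        t_map[idx] = pr["t_obs"]
        tf_map = np.zeros(grid.shape)
        tf_map[idx] = pr["tfce_obs"]
        p_map = np.ones(grid.shape)
        p_map[idx] = pvals
        cm = ContrastMaps(
            name=name,
            t_map=grid.like(t_map),
            tfce_map=grid.like(tf_map),
            fwe_p_map=grid.like(p_map),
            neglogp_map=grid.like(neglog10_array(p_map)),
        )
        contrast_maps[name] = cm
        cl = extract_clusters(cm.fwe_p_map, cm.t_map, mask, params)
        cl.insert(0, "contrast", name)
        cluster_frames.append(cl)
    non_empty = [f for f in cluster_frames if len(f)]
    clusters = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else (cluster_frames[0] if cluster_frames else pd.DataFrame())
    )
    return TfceResult(
        contrasts=contrast_maps, clusters=clusters, null_max=null_max, params=params
    )


def neglog10_array(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    return -np.log10(p)


def neglog10(p_map: VolumeGrid) -> VolumeGrid:
    """Per-voxel -log10(p) for display (-log10(0.05) ~ 1.3)."""
    return p_map.like(neglog10_array(p_map.data))


def extract_clusters(
    fwe_p_map: VolumeGrid,
    t_map: VolumeGrid,
    mask: RegionMask,
    params: TfceParams | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Connected components of {FWE p < alpha} with local-maxima rows.

    One peak (maximum t) per connected component; coordinates are world
    mm from the affine; volume = voxel count x voxel volume.
    """
    params = params or TfceParams()
    alpha = params.alpha if alpha is None else alpha
    sig = np.zeros(fwe_p_map.shape, dtype=bool)
    idx = tuple(mask.voxels.T)
    sig[idx] = fwe_p_map.data[idx] < alpha
    labels, n_lab = ndimage.label(sig, structure=_structure(params.connectivity))
    rows = []
    vox_vol = fwe_p_map.voxel_volume_mm3
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        tvals = t_map.data[tuple(vox.T)]
        peak = vox[int(np.argmax(tvals))]
        mm = (fwe_p_map.affine @ np.append(peak, 1.0))[:3]
        rows.append(
            {
                "x_mm": float(mm[0]),
                "y_mm": float(mm[1]),
                "z_mm": float(mm[2]),
                "n_voxels": int(len(vox)),
                "volume_mm3": float(len(vox) * vox_vol),
                "peak_t": float(tvals.max()),
                "min_fwe_p": float(fwe_p_map.data[tuple(vox.T)].min()),
            }
        )
    cols = ["x_mm", "y_mm", "z_mm", "n_voxels", "volume_mm3", "peak_t", "min_fwe_p"]
    return pd.DataFrame(rows, columns=cols)
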