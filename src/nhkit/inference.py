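"""Voxelwise group inference on NH maps with GRF cluster-extent correction.

A per-voxel general linear model tests the three-group effect (ANCOVA F,
adjusting for mean-centered covariates) and pairwise group contrasts (t).
Residual spatial smoothness is estimated from the standardized GLM residuals,
converted to resels, and clusters of suprathreshold voxels receive family-wise
corrected p-values from the standard Gaussian-random-field expected-cluster
formulas (t/F maps Gaussianized through the probit transform of the voxel
p-value).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "StatMap",
    "SmoothnessEstimate",
    "ClusterTable",
    "build_design",
    "voxelwise_glm",
    "estimate_smoothness",
    "grf_cluster_correct",
    "cluster_report",
    "extract_cluster_nh",
]

LN2_4 = 4.0 * np.log(2.0)


@dataclass
class DesignMatrix:
    """Subjects x predictors design with named columns.

    Group indicator columns (cell means) come first, then mean-centered
    covariates; no explicit intercept column (the group indicators span it).
    """

    matrix: np.ndarray
    columns: list[str]
    groups: list[str]          # group column names, in order
    group_of: np.ndarray       # per-subject group label

    def contrast(self, group_a: str, group_b: str) -> np.ndarray:
        """Contrast vector for mean(group_a) - mean(group_b), covariates zero."""
        c = np.zeros(self.matrix.shape[1])
        c[self.columns.index(group_a)] = 1.0
        c[self.columns.index(group_b)] = -1.0
        return c


def build_design(
    table: pd.DataFrame,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "education", "mean_fd"),
) -> DesignMatrix:
    """Cell-means group coding plus mean-centered covariates."""
    groups = list(dict.fromkeys(table[group_col]))
    cols, names = [], []
    for g in groups:
        cols.append((table[group_col] == g).to_numpy(float))
        names.append(g)
    for cov in covariates:
        v = table[cov].to_numpy(float)
        if np.isnan(v).any():
            raise ValueError(f"covariate {cov} contains missing values")
        cols.append(v - v.mean())
        names.append(cov)
    x = np.column_stack(cols)
    return DesignMatrix(x, names, groups, table[group_col].to_numpy())


@dataclass
class StatMap:
    stat: np.ndarray           # 3D
    df: tuple[float, float] | float
    stat_type: str             # "t" or "F"
    mask: np.ndarray
    affine: np.ndarray
    comparison: str = ""


@dataclass(frozen=True)
class SmoothnessEstimate:
    fwhm_mm: tuple[float, float, float]
    fwhm_vox: tuple[float, float, float]
    resel_count: float
    n_voxels: int


@dataclass
class ClusterTable:
    rows: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        cols = ["comparison", "label", "x_mm", "y_mm", "z_mm",
                "n_voxels", "peak_stat", "sign", "p_corrected"]
        return pd.DataFrame(self.rows, columns=cols)


def _prune_design(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("design rank-deficient; dropping columns %s", dropped)
        warnings.warn(f"dropped collinear design columns: {dropped}", stacklevel=3)
    return x[:, keep], [n for n, k in zip(names, keep) if k], dropped


def voxelwise_glm(
    nh_stack: np.ndarray,
    design: DesignMatrix,
    contrast: tuple[str, str] | None = None,
    mask: np.ndarray | None = None,
) -> tuple[StatMap, np.ndarray]:
    """OLS fit of ``nh_stack`` (subjects x voxels, in-mask columns) per voxel.

    With ``contrast=(a, b)`` returns the pairwise t map for mean(a) - mean(b)
    adjusted for covariates; otherwise the omnibus group F (full model vs
    covariates-plus-intercept). Also returns the residual stack for
    smoothness estimation.
    """
    y = np.asarray(nh_stack, dtype=np.float64)
    x, names, _ = _prune_design(design.matrix, list(design.columns))
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("nh_stack rows must match design rows")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df_den = n - p
    sigma2 = (resid**2).sum(axis=0) / df_den

    if contrast is not None:
        a, b = contrast
        for g in (a, b):
            if g not in names:
                raise ValueError(f"group column {g!r} missing after pruning")
        c = np.zeros(p)
        c[names.index(a)] = 1.0
        c[names.index(b)] = -1.0
        xtx_inv = np.linalg.pinv(x.T @ x)
        var_c = float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = (c @ beta) / np.sqrt(sigma2 * var_c)
        tvals = np.nan_to_num(tvals)
        stat, df, kind, tag = tvals, float(df_den), "t", f"{a} vs {b}"
    else:
        group_cols = [names.index(g) for g in design.groups if g in names]
        if len(group_cols) < 2:
            raise ValueError("need at least two group columns for the omnibus F")
        # reduced model: intercept + covariates
        keep = [j for j in range(p) if j not in group_cols]
        x0 = np.column_stack([np.ones(n)] + ([x[:, keep]] if keep else []))
        x0, _, _ = _prune_design(x0, [f"c{j}" for j in range(x0.shape[1])])
        beta0 = np.linalg.pinv(x0) @ y
        rss0 = ((y - x0 @ beta0) ** 2).sum(axis=0)
        rss = (resid**2).sum(axis=0)
        df_num = p - x0.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            fvals = ((rss0 - rss) / df_num) / (rss / df_den)
        fvals = np.nan_to_num(fvals)
        stat, df, kind, tag = fvals, (float(df_num), float(df_den)), "F", "omnibus"

    if mask is not None:
        vol = np.zeros(mask.shape)
        vol[mask] = stat
    else:
        vol = stat
    return StatMap(vol, df, kind, mask if mask is not None else np.ones_like(vol, bool),
                   np.eye(4), tag), resid


def estimate_smoothness(
    residual_stack: np.ndarray,
    mask: np.ndarray,
    voxel_sizes_mm: tuple[float, float, float] | np.ndarray = (3.0, 3.0, 3.0),
) -> SmoothnessEstimate:
    """Per-axis smoothness (FWHM) of the residual fields.

    Residual maps are variance-normalized per voxel, the lag-1 variance of
    spatial differences v_i = var(u(x+e_i) - u(x)) is pooled over maps, and a
    Gaussian autocorrelation is inverted: rho_i = 1 - v_i/2, FWHM_i =
    sqrt(-2 ln 2 / ln rho_i) voxels. The per-axis FWHM is floored at one voxel
    (the resel count never exceeds the voxel count); fields rougher than the
    lattice therefore report exactly one voxel.
    """
    res = np.asarray(residual_stack, dtype=np.float64)
    if res.ndim != 2 or res.shape[0] < 3:
        raise ValueError("need a (maps x voxels) stack with at least 3 maps")
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if res.shape[1] != n_vox:
        raise ValueError("residual columns must match mask voxels")
    sd = res.std(axis=0)
    sd[sd == 0] = 1.0
    u = res / sd

    vols = np.zeros((res.shape[0], *mask.shape))
    vols[:, mask] = u
    fwhm_vox = []
    for axis in range(3):
        m1 = mask & np.roll(mask, -1, axis=axis)
        m1[tuple(slice(None) if a != axis else slice(-1, None) for a in range(3))] = False
        if not m1.any():
            fwhm_vox.append(1.0)
            continue
        d = np.take(vols, range(1, mask.shape[axis]), axis=axis + 1) - \
            np.take(vols, range(0, mask.shape[axis] - 1), axis=axis + 1)
        pair_mask = np.take(m1, range(0, mask.shape[axis] - 1), axis=axis)
        v = float((d[:, pair_mask] ** 2).mean())
        rho = 1.0 - v / 2.0
        if rho <= 0:
            fwhm_vox.append(1.0)
        else:
            fwhm_vox.append(max(1.0, float(np.sqrt(-2.0 * np.log(2.0) / np.log(rho)))))
    voxel_sizes_mm = np.asarray(voxel_sizes_mm, dtype=float)
    fwhm_mm = tuple(float(f * s) for f, s in zip(fwhm_vox, voxel_sizes_mm))
    resels = n_vox / float(np.prod(fwhm_vox))
    return SmoothnessEstimate(fwhm_mm, tuple(map(float, fwhm_vox)), resels, n_vox)


# ---------------------------------------------------------------------------
# GRF cluster-extent correction
# ---------------------------------------------------------------------------

def _stat_threshold(stat_type: str, df, voxel_p: float) -> float:
    if stat_type == "t":
        return float(stats.t.isf(voxel_p, df))
    if stat_type == "F":
        return float(stats.f.isf(voxel_p, *df))
    if stat_type == "z":
        return float(stats.norm.isf(voxel_p))
    raise ValueError(f"unknown stat type {stat_type!r}")


def _expected_clusters_3d(u: float, resels: float) -> float:
    """Expected number of clusters above Gaussianized threshold u (3D EC term)."""
    return resels * LN2_4**1.5 * (2.0 * np.pi) ** -2 * (u**2 - 1.0) * np.exp(-(u**2) / 2.0)


def grf_cluster_p(k_voxels: int, u: float, resels: float, n_mask_voxels: int,
                  voxel_p: float) -> float:
    """Corrected p for a cluster of ``k_voxels`` at Gaussianized threshold u."""
    em = _expected_clusters_3d(u, resels)
    if em <= 0:
        return 1.0
    en = n_mask_voxels * voxel_p / em  # expected cluster size in voxels
    beta = (math.gamma(2.5) / en) ** (2.0 / 3.0)
    p_ge_k = np.exp(-beta * k_voxels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_ge_k))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def grf_cluster_correct(
    stat_map: StatMap,
    smoothness: SmoothnessEstimate,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    mask: np.ndarray | None = None,
    connectivity: int = 26,
    two_sided: bool = True,
) -> ClusterTable:
    """Threshold a stat map at the voxel-level p, form connected clusters and
    keep those whose GRF-corrected extent p falls below ``cluster_p``.

    t (and z) maps are processed one tail at a time when ``two_sided``; F maps
    have a single positive tail. Peak coordinates are voxel indices here;
    :func:`cluster_report` converts to mm and attaches labels.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
    mask = stat_map.mask if mask is None else np.asarray(mask, bool)
    structure = _connectivity_structure(connectivity)
    u_gauss = float(stats.norm.isf(voxel_p))
    thr = _stat_threshold(stat_map.stat_type, stat_map.df, voxel_p)
    n_mask = int(mask.sum())

    tails: list[tuple[int, np.ndarray]] = [(1, stat_map.stat)]
    if stat_map.stat_type in ("t", "z") and two_sided:
        tails.append((-1, -stat_map.stat))

    table = ClusterTable()
    for sign, vol in tails:
        supra = (vol > thr) & mask
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            voxels = np.argwhere(labels == lab)
            k = voxels.shape[0]
            p_corr = grf_cluster_p(k, u_gauss, smoothness.resel_count, n_mask, voxel_p)
            if p_corr >= cluster_p:
                continue
            vals = vol[tuple(voxels.T)]
            peak = voxels[np.argmax(vals)]
            table.rows.append(
                {
                    "comparison": stat_map.comparison,
                    "label": "",
                    "peak_ijk": tuple(int(i) for i in peak),
                    "voxels": voxels,
                    "n_voxels": int(k),
                    "peak_stat": float(sign * vals.max()),
                    "sign": int(sign),
                    "p_corrected": float(p_corr),
                }
            )
    return table


def cluster_report(
    table: ClusterTable,
    affine: np.ndarray,
    label_atlas: np.ndarray | None = None,
    atlas_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Convert peak voxel indices to mm, attach region labels (majority overlap
    with the atlas parcellation) and sort by comparison then extent."""
    affine = np.asarray(affine, dtype=float)
    rows = []
    for r in table.rows:
        ijk = np.asarray(r["peak_ijk"])
        mm = affine[:3, :3] @ ijk + affine[:3, 3]
        label = r.get("label", "")
        if label_atlas is not None:
            ids = label_atlas[tuple(r["voxels"].T)]
            ids = ids[ids > 0]
            if ids.size:
                winner = int(np.bincount(ids).argmax())
                label = atlas_names.get(winner, str(winner)) if atlas_names else str(winner)
            else:
                label = "unlabeled"
        rows.append(
            {
                "comparison": r["comparison"],
                "label": label,
                "x_mm": float(mm[0]),
                "y_mm": float(mm[1]),
                "z_mm": float(mm[2]),
                "n_voxels": r["n_voxels"],
                "peak_stat": r["peak_stat"],
                "sign": r["sign"],
                "p_corrected": r["p_corrected"],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["comparison", "label", "x_mm", "y_mm", "z_mm",
                 "n_voxels", "peak_stat", "sign", "p_corrected"],
    )
    if len(df):
        df = df.sort_values(["comparison", "n_voxels"], ascending=[True, False]).reset_index(drop=True)
    return df


def extract_cluster_nh(nh_stack: np.ndarray, mask: np.ndarray, cluster_voxels: np.ndarray) -> np.ndarray:
    """Per-subject mean NH over a cluster.

    nh_stack is subjects x in-mask-voxels (C-order over ``mask``);
    cluster_voxels is an (k, 3) voxel index array lying inside the mask.
    """
    cluster_voxels = np.asarray(cluster_voxels)
    if cluster_voxels.size == 0:
        raise ValueError("empty cluster")
    flat_idx = np.ravel_multi_index(cluster_voxels.T, mask.shape)
    mask_flat = np.flatnonzero(mask.reshape(-1))
    pos = np.searchsorted(mask_flat, flat_idx)
    if (pos >= mask_flat.size).any() or (mask_flat[pos] != flat_idx).any():
        raise ValueError("cluster extends outside the mask")
    return nh_stack[:, pos].mean(axis=1)
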