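"""Network homogeneity (NH) maps.

For every voxel v inside a network mask, NH(v) is the mean Pearson correlation
between v's time series and the time series of every *other* in-mask voxel.
The map is computed with an O(m*T) standardized-series matrix formulation and
optionally smoothed with a mask-renormalized Gaussian kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import BoldRun

logger = logging.getLogger(__name__)

__all__ = ["NHMap", "compute_nh", "compute_nh_pairwise", "nh_values", "smooth_map"]

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Kernel truncation (in sigmas) for mask-renormalized smoothing. Wide enough
#: that the discrete kernel carries its full mass to ~1e-9.
_SMOOTH_TRUNCATE = 6.0


@dataclass
class NHMap:
    """Per-subject NH map; ``values`` is defined on mask voxels, zero outside."""

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def in_mask(self) -> np.ndarray:
        """Vector of NH values at mask voxels (C-order)."""
        return self.values[self.mask]


def _standardize_columns(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columns scaled to zero mean / unit L2 norm; flags zero-variance columns."""
    centered = series - series.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    degenerate = norms < 1e-300
    safe = np.where(degenerate, 1.0, norms)
    return centered / safe, degenerate


def nh_values(series: np.ndarray) -> np.ndarray:
    """NH for each column of a T x m series matrix.

    NH_v = mean_{u != v} corr(series[:, v], series[:, u]). Zero-variance
    columns get NH = 0 and contribute nothing to the others' averages.
    """
    t, m = series.shape
    if m < 2:
        raise ValueError("NH needs at least 2 voxels")
    z, degenerate = _standardize_columns(np.asarray(series, dtype=np.float64))
    n_bad = int(degenerate.sum())
    if n_bad:
        logger.warning("%d zero-variance voxel(s) set to NH=0", n_bad)
        z[:, degenerate] = 0.0
    total = z.sum(axis=1)
    # sum over u of r_vu, including r_vv = 1 for valid columns
    rowsum = z.T @ total
    valid = ~degenerate
    m_valid = int(valid.sum())
    nh = np.zeros(m)
    if m_valid >= 2:
        nh[valid] = (rowsum[valid] - 1.0) / (m_valid - 1)
    return nh


def compute_nh(run: BoldRun, mask: np.ndarray, subject_id: str = "") -> NHMap:
    """NH map of a preprocessed run within a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.shape3d:
        raise ValueError(f"mask shape {mask.shape} does not match run {run.shape3d}")
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    series = run.data[mask].T  # T x m
    values = np.zeros(run.shape3d)
    values[mask] = nh_values(series)
    return NHMap(values=values, mask=mask, affine=run.affine, subject_id=subject_id)


def compute_nh_pairwise(series: np.ndarray) -> np.ndarray:
    """Literal O(m^2) double loop over voxel pairs; oracle for :func:`nh_values`."""
    t, m = series.shape
    nh = np.zeros(m)
    for v in range(m):
        acc = 0.0
        for u in range(m):
            if u == v:
                continue
            acc += np.corrcoef(series[:, v], series[:, u])[0, 1]
        nh[v] = acc / (m - 1)
    return nh


def smooth_map(nh_map: NHMap, fwhm_mm: float) -> NHMap:
    """Gaussian smoothing restricted to the mask, renormalized at mask edges
    so constants are preserved. ``fwhm_mm=0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return NHMap(nh_map.values.copy(), nh_map.mask, nh_map.affine, nh_map.subject_id)
    voxel_mm = np.sqrt((np.asarray(nh_map.affine)[:3, :3] ** 2).sum(axis=0))
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / voxel_mm
    maskf = nh_map.mask.astype(np.float64)
    num = gaussian_filter(nh_map.values * maskf, sigma=sigma_vox, mode="constant", truncate=_SMOOTH_TRUNCATE)
    den = gaussian_filter(maskf, sigma=sigma_vox, mode="constant", truncate=_SMOOTH_TRUNCATE)
    out = np.zeros_like(nh_map.values)
    inside = nh_map.mask
    out[inside] = num[inside] / den[inside]
    return NHMap(out, nh_map.mask, nh_map.affine, nh_map.subject_id)
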