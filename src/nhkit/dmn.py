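"""Default-mode-network mask construction by group spatial ICA.

Two-stage reduction (per-subject temporal PCA, then group-level PCA of the
temporally concatenated reduced data), fixed-point ICA unmixing of the group
spatial sources, dual-regression back-reconstruction of subject maps,
template-driven component selection, and per-group overlay into a binary
network mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .preprocess import BoldRun

logger = logging.getLogger(__name__)

__all__ = ["ICAResult", "NetworkMask", "group_ica", "select_dmn_components", "build_mask"]


@dataclass
class ICAResult:
    """Group spatial ICA output.

    component_maps : (C, V) group-level spatial maps, z-scored within the
        analysis mask, sign-fixed so each map's skewness is positive.
    subject_maps : (S, C, V) back-reconstructed per-subject maps (z-scored).
    subject_loadings : (S, T, C) per-subject component time courses.
    """

    component_maps: np.ndarray
    subject_maps: np.ndarray
    subject_loadings: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def n_components(self) -> int:
        return self.component_maps.shape[0]

    def map_volume(self, c: int) -> np.ndarray:
        return self.component_maps[c].reshape(self.grid_shape)


@dataclass
class NetworkMask:
    mask: np.ndarray  # boolean 3D
    affine: np.ndarray
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("network mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _zscore_maps(maps: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance rows with positive skewness."""
    z = maps - maps.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    flip = stats.skew(z, axis=1) < 0
    z[flip] *= -1.0
    return z


def _temporal_pca(x: np.ndarray, k: int) -> np.ndarray:
    """Reduce a T x V matrix to its k leading temporal PCs (k x V)."""
    xc = x - x.mean(axis=0)
    cov = (xc @ xc.T) / xc.shape[1]  # T x T
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order].T @ xc


def group_ica(
    runs: list[BoldRun],
    n_components: int = 20,
    seed: int = 0,
    subject_pcs: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ICAResult:
    """Group spatial ICA over runs sharing one grid.

    Per-subject temporal PCA keeps ``subject_pcs`` components (default
    ``ceil(1.5 * n_components)`` capped by T); the reduced data are stacked
    across subjects, reduced again to ``n_components`` and unmixed with
    seeded FastICA. Subject maps come back by dual regression.
    """
    if len(runs) < 2:
        raise ValueError("group ICA needs at least 2 runs")
    grid = runs[0].shape3d
    if any(r.shape3d != grid for r in runs):
        raise ValueError("all runs must share one grid")
    t_min = min(r.n_volumes for r in runs)
    if subject_pcs is None:
        subject_pcs = int(np.ceil(1.5 * n_components))
    subject_pcs = min(subject_pcs, t_min - 1)
    if n_components > subject_pcs * len(runs):
        raise ValueError("n_components exceeds the reduced data rank")
    v = int(np.prod(grid))

    reduced = np.concatenate(
        [
            _temporal_pca(r.data.reshape(v, r.n_volumes).T.astype(np.float64), subject_pcs)
            for r in runs
        ],
        axis=0,
    )  # (S*k) x V
    group_pcs = _temporal_pca(reduced, n_components)  # C x V

    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
        sources = ica.fit_transform(group_pcs.T).T  # C x V spatial sources
    maps = _zscore_maps(sources)

    pinv_maps = np.linalg.pinv(maps)  # V x C
    subject_maps = np.empty((len(runs), n_components, v))
    loadings = []
    for s, r in enumerate(runs):
        x = r.data.reshape(v, r.n_volumes).T.astype(np.float64)
        x = x - x.mean(axis=0)
        tc = x @ pinv_maps  # T x C
        beta, *_ = np.linalg.lstsq(tc, x, rcond=None)  # C x V
        subject_maps[s] = _zscore_maps(beta)
        loadings.append(tc)
    return ICAResult(maps, subject_maps, np.asarray(loadings), grid, runs[0].affine)


def select_dmn_components(
    ica: ICAResult, template: np.ndarray, match_threshold: float = 0.3
) -> tuple[list[int], np.ndarray]:
    """Rank components by absolute spatial correlation with the template.

    Returns indices of all components above ``match_threshold``; the best
    match is always returned even below threshold (with a warning).
    """
    tpl = np.asarray(template, dtype=np.float64).reshape(-1)
    if tpl.size != ica.component_maps.shape[1]:
        raise ValueError("template grid does not match ICA maps")
    tplc = tpl - tpl.mean()
    denom_t = np.linalg.norm(tplc)
    scores = np.empty(ica.n_components)
    for c in range(ica.n_components):
        m = ica.component_maps[c]
        scores[c] = abs(m @ tplc) / (np.linalg.norm(m) * denom_t + 1e-300)
    selected = [int(c) for c in np.argsort(scores)[::-1] if scores[c] >= match_threshold]
    if not selected:
        best = int(np.argmax(scores))
        logger.warning(
            "no component reached match threshold %.2f; falling back to argmax "
            "(component %d, |r|=%.3f)", match_threshold, best, scores[best],
        )
        selected = [best]
    return selected, scores


def build_mask(
    ica: ICAResult,
    selected: list[int],
    group_assignments: list[str] | np.ndarray,
    z_threshold: float = 1.0,
    region_labels: np.ndarray | None = None,
) -> NetworkMask:
    """Overlay rule: for each group, average the subjects' z-scored maps of
    each selected component and keep voxels above ``z_threshold``; the final
    mask is the union over components and groups."""
    if not selected:
        raise ValueError("no components selected")
    groups = np.asarray(group_assignments)
    if groups.shape[0] != ica.subject_maps.shape[0]:
        raise ValueError("group assignment length does not match subjects")
    mask_flat = np.zeros(ica.subject_maps.shape[2], dtype=bool)
    for g in np.unique(groups):
        gm = ica.subject_maps[groups == g].mean(axis=0)  # C x V
        for c in selected:
            mask_flat |= gm[c] > z_threshold
    mask = mask_flat.reshape(ica.grid_shape)
    if not mask.any():
        raise ValueError("resulting network mask is empty; lower z_threshold")
    return NetworkMask(mask, ica.affine, region_labels)
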