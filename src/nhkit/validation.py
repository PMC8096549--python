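"""Calibration and recovery studies run on the package's own machinery.

These routines quantify, from scratch, how well the pipeline recovers known
ground truth: the family-wise error rate of the GRF cluster correction on
simulated smooth null fields, the recovery of the planted NH/anhedonia-score
correlation at the region level, and the recovery of a planted discriminative
feature pair by the exhaustive LOOCV-SVM search. They are used by the test
suite and by the results-reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .classify import enumerate_combinations
from .clinical import bh_adjust, pearson_corr
from .inference import StatMap, estimate_smoothness, grf_cluster_correct
from .nh import FWHM_TO_SIGMA, compute_nh
from .preprocess import BoldRun, PreprocessConfig, preprocess_run
from .synthetic import Cohort, CohortSpec, RegionSpec, SyntheticSubject, generate_cohort

__all__ = [
    "simulate_grf_fwer",
    "network_region_nh_table",
    "correlation_recovery_replicate",
    "planted_classification_cohort",
    "planted_classification_recovery",
    "planted_pair_majority",
]


# ---------------------------------------------------------------------------
# GRF family-wise error rate under the null
# ---------------------------------------------------------------------------

def simulate_grf_fwer(
    n_replicates: int = 500,
    grid: tuple[int, int, int] = (24, 28, 22),
    fwhm_mm: float = 6.0,
    voxel_size_mm: float = 3.0,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_smoothness_fields: int = 20,
    seed: int = 0,
) -> float:
    """Fraction of null replicates with at least one surviving cluster.

    Each replicate draws ``n_smoothness_fields`` smooth Gaussian fields to
    estimate smoothness (as the pipeline does from residuals) plus one
    independent field playing the role of the statistic map, thresholds it
    one-sided at ``voxel_p`` and applies the cluster-extent correction.
    """
    rng = np.random.default_rng(seed)
    sigma = fwhm_mm / voxel_size_mm / FWHM_TO_SIGMA
    mask = np.ones(grid, bool)

    def field():
        f = gaussian_filter(rng.standard_normal(grid), sigma, mode="constant", truncate=6)
        return f / f.std()

    hits = 0
    for _ in range(n_replicates):
        stack = np.asarray([field()[mask] for _ in range(n_smoothness_fields)])
        est = estimate_smoothness(stack, mask, (voxel_size_mm,) * 3)
        zmap = StatMap(field(), float("inf"), "z", mask, np.eye(4))
        table = grf_cluster_correct(zmap, est, voxel_p, cluster_p, mask, two_sided=False)
        hits += len(table) > 0
    return hits / n_replicates


# ---------------------------------------------------------------------------
# region-level NH measurement through the preprocessing pipeline
# ---------------------------------------------------------------------------

def _compact_subject_run(subject: SyntheticSubject, cohort: Cohort):
    """Rearrange the network + WM/CSF voxels of a subject's run into a compact
    (n, 1, 1, t) volume. Every preprocessing stage acts per voxel in time, so
    statistics computed on the compact run equal those on the full volume."""
    spec = cohort.spec
    flat = subject.bold.data.reshape(-1, subject.bold.n_volumes)
    net_idx = np.concatenate([r.index(spec.grid_shape) for r in spec.regions])
    wm_idx = np.flatnonzero(cohort.wm_mask.reshape(-1))
    csf_idx = np.flatnonzero(cohort.csf_mask.reshape(-1))
    data = flat[np.concatenate([net_idx, wm_idx, csf_idx])]
    n = data.shape[0]
    run = BoldRun(data.reshape(n, 1, 1, -1), subject.bold.affine, spec.tr_s)
    sel = np.zeros((n, 1, 1), bool)
    net = sel.copy()
    net[: len(net_idx)] = True
    wm = sel.copy()
    wm[len(net_idx) : len(net_idx) + len(wm_idx)] = True
    csf = sel.copy()
    csf[len(net_idx) + len(wm_idx) :] = True
    return run, net, wm, csf


def network_region_nh_table(
    cohort: Cohort,
    group: str | None = None,
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Per-subject region-mean NH measured over the whole network after full
    temporal preprocessing (one column per region, indexed like the subject
    table); rows for motion-excluded subjects are dropped."""
    spec = cohort.spec
    config = config or PreprocessConfig()
    sizes = [r.size for r in spec.regions]
    offsets = np.cumsum([0] + sizes)
    rows, ids = [], []
    for subject in cohort.subjects:
        if group is not None and subject.group != group:
            continue
        run, net, wm, csf = _compact_subject_run(subject, cohort)
        res = preprocess_run(run, subject.motion, config, wm_mask=wm, csf_mask=csf)
        if not res.decision.keep:
            continue
        nh = compute_nh(res.run, net).in_mask()
        rows.append([nh[a:b].mean() for a, b in zip(offsets[:-1], offsets[1:])])
        ids.append(subject.subject_id)
    return pd.DataFrame(rows, columns=[r.label for r in spec.regions], index=ids)


def correlation_recovery_replicate(
    seed: int,
    score: str = "teps_total",
    spec: CohortSpec | None = None,
) -> dict:
    """One seeded replicate of the planted NH/score correlation recovery.

    Generates a fresh cohort (melancholic group at the reference size), runs
    the temporal pipeline on the network voxels, extracts each region's mean
    NH, correlates the coupling region's NH with the designated score across
    melancholic subjects, and BH-adjusts across the region family per score.
    """
    if spec is None:
        spec = CohortSpec(group_sizes=(31, 2, 2), seed=seed)
    else:
        spec = replace(spec, seed=seed)
    cohort = generate_cohort(spec)
    group = spec.nh_corr_group
    nh = network_region_nh_table(cohort, group=group)
    table = cohort.table.set_index("subject_id").loc[nh.index]
    fam = []
    for region in nh.columns:
        r, p, n = pearson_corr(nh[region].to_numpy(), table[score].to_numpy())
        fam.append((region, r, p, n))
    p_bh = bh_adjust([f[2] for f in fam])
    out = {region: {"r": r, "p_raw": p, "p_bh": float(pb), "n": n}
           for (region, r, p, n), pb in zip(fam, p_bh)}
    hit = out[spec.nh_corr_region]
    return {"regions": out, "r": hit["r"], "p_bh": hit["p_bh"],
            "recovered": hit["r"] < 0 and hit["p_bh"] < 0.05}


# ---------------------------------------------------------------------------
# planted-signal classification recovery
# ---------------------------------------------------------------------------

def planted_classification_cohort(seed: int = 0):
    """Cohort whose discriminative signal between the two patient groups is
    planted in the left SMFG and left ITG (the right SMFG and the remaining
    regions carry no or weak between-patient differences)."""
    overrides = {
        "smfg_r": {"melancholic": 0.42, "nonmelancholic": 0.42},  # neutralized
        "smfg_l": {"melancholic": 0.53, "nonmelancholic": 0.28},
        "itg_l": {"melancholic": 0.26, "nonmelancholic": 0.48},
    }
    regions = []
    for r in CohortSpec(group_sizes=(2, 2, 2)).regions:
        cbg = dict(r.coupling_by_group)
        cbg.update(overrides.get(r.label, {}))
        regions.append(RegionSpec(r.label, r.voxels, cbg))
    # larger patient groups than the reference cohort: the recovery question
    # is about the subset search, so LOOCV estimation noise is damped rather
    # than emulated
    return CohortSpec(group_sizes=(90, 90, 2), regions=regions, seed=seed)


def planted_classification_recovery(seed: int = 0, max_subset: int = 2):
    """Recover the planted feature pair: region-mean NH features for the two
    patient groups, exhaustive LOOCV-SVM subset search, best combination."""
    spec = planted_classification_cohort(seed)
    cohort = generate_cohort(spec)
    nh = network_region_nh_table(cohort)
    table = cohort.table.set_index("subject_id").loc[nh.index]
    patients = table["group"].isin(["melancholic", "nonmelancholic"]).to_numpy()
    feats = nh.loc[patients, ["smfg_l", "smfg_r", "itg_l"]]
    labels = table["group"].to_numpy()[patients]
    results, best = enumerate_combinations(feats, labels, max_subset=max_subset)
    return results, best


def planted_pair_majority(seed: int = 0, n_replicates: int = 3) -> float:
    """Fraction of seeded planted-signal cohorts whose best combination is the
    planted left-SMFG + left-ITG pair."""
    hits = 0
    for i in range(n_replicates):
        _, best = planted_classification_recovery(seed=(seed + 7919 * i) % (2**31))
        hits += set(best.features) == {"smfg_l", "itg_l"}
    return hits / n_replicates
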