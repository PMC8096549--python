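"""Synthetic three-group resting-state cohort with known ground truth.

Generates everything the analysis pipeline consumes — 4D BOLD runs, rigid-body
motion traces, and a clinical/demographic subject table — for a melancholic
MDD / nonmelancholic MDD / healthy-control study design.

The BOLD model is deliberately simple and analytically checkable: each network
region r has one latent time course L_r per subject, and every voxel v inside
the region follows

    x_v(t) = noise_sd * ( sqrt(rho) * L_r(t) + sqrt(1 - rho) * eps_v(t) )

with L_r and eps_v i.i.d. standard normal, so the population correlation of
any two within-region voxels is exactly rho and the population network
homogeneity of the region equals rho. Group differences are planted by giving
each group its own rho per region; per-subject heterogeneity comes from a
Gaussian jitter on rho. Voxels outside every region are pure noise.

Clinical scores are Gaussian with configurable per-group means/SDs. Designated
scores are coupled to a designated region's realized network homogeneity: the
score is a linear function of the subject's realized (band-limited, detrended)
region-mean NH plus orthogonalized Gaussian noise, calibrated so the sample
correlation across the group equals the target exactly. Healthy controls carry
no TEPS scores (emitted as missing values).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BoldRun, MotionTrace, _bandpass_series, _detrend_series, friston24
from .nh import nh_values

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSpec",
    "CohortSpec",
    "SyntheticSubject",
    "Cohort",
    "default_regions",
    "default_clinical_params",
    "make_affine",
    "generate_bold",
    "generate_motion",
    "generate_clinical",
    "generate_cohort",
    "analysis_ready_region_nh",
    "network_nh_from_subject",
]

GROUPS = ("melancholic", "nonmelancholic", "control")

#: Clinical scales carried in the subject table. TEPS scales are patient-only.
SCALES = (
    "hrsd17",
    "bai",
    "shapsc",
    "teps_total",
    "teps_abstract_anticipatory",
    "teps_contextual_anticipatory",
    "teps_abstract_consummatory",
    "teps_contextual_consummatory",
)


@dataclass(frozen=True)
class RegionSpec:
    """A labeled set of grid voxels sharing one latent signal.

    coupling_by_group maps group name -> within-region pairwise correlation rho.
    """

    label: str
    voxels: np.ndarray  # (m, 3) int voxel coordinates
    coupling_by_group: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=np.intp))
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError(f"region {self.label}: voxels must be (m, 3)")
        for g, rho in self.coupling_by_group.items():
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"region {self.label}, group {g}: rho={rho} not in [0, 1)")

    @property
    def size(self) -> int:
        return self.voxels.shape[0]

    def index(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        return np.ravel_multi_index(self.voxels.T, grid_shape)


def _box(x0: int, x1: int, y0: int, y1: int, z0: int, z1: int) -> np.ndarray:
    """Inclusive-bound rectangular voxel block."""
    g = np.mgrid[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1]
    return g.reshape(3, -1).T


def default_regions() -> list[RegionSpec]:
    """Six default-mode regions on the default 24 x 28 x 22 grid.

    Couplings plant the study's group-difference pattern: both patient groups
    up in right PCC/precuneus and right angular gyrus and down in right MTG
    relative to controls; melancholic-specific decrease in left ITG and
    increase in bilateral SMFG (with the nonmelancholic group below controls
    in SMFG). Extents sit in the 22-83 voxel range typical of the reported
    clusters.
    """
    c = lambda hc, mel, non: {"control": hc, "melancholic": mel, "nonmelancholic": non}
    return [
        RegionSpec("pcc_precuneus_r", _box(12, 15, 6, 9, 13, 15), c(0.40, 0.56, 0.56)),
        RegionSpec("angular_r", _box(18, 21, 5, 8, 15, 17), c(0.40, 0.55, 0.55)),
        RegionSpec("mtg_r", _box(18, 20, 12, 17, 5, 7), c(0.45, 0.24, 0.24)),
        RegionSpec("itg_l", _box(3, 6, 11, 15, 3, 5), c(0.47, 0.23, 0.47)),
        RegionSpec("smfg_l", _box(6, 9, 22, 25, 11, 13), c(0.40, 0.55, 0.24)),
        RegionSpec("smfg_r", _box(14, 17, 22, 25, 11, 13), c(0.42, 0.54, 0.31)),
    ]


def default_clinical_params() -> dict[str, dict[str, tuple[float, float] | None]]:
    """Per-scale (mean, SD) by group; None marks a scale a group does not take."""
    mk = lambda mel, non, hc: {"melancholic": mel, "nonmelancholic": non, "control": hc}
    return {
        "age": mk((28.65, 5.30), (32.04, 8.18), (29.59, 5.00)),
        "education": mk((15.16, 3.20), (12.54, 3.00), (14.59, 2.82)),
        "illness_duration": mk((6.75, 4.26), (5.96, 4.64), None),
        "hrsd17": mk((21.77, 3.79), (21.00, 3.14), (0.94, 0.95)),
        "bai": mk((44.00, 11.51), (38.77, 9.84), (22.63, 2.28)),
        "shapsc": mk((37.23, 6.04), (31.89, 5.24), (21.59, 5.36)),
        "teps_total": mk((58.30, 14.19), (69.46, 11.16), None),
        "teps_abstract_anticipatory": mk((13.17, 4.79), (17.04, 3.85), None),
        "teps_contextual_anticipatory": mk((13.13, 3.96), (16.68, 3.64), None),
        "teps_abstract_consummatory": mk((20.20, 5.21), (22.39, 5.28), None),
        "teps_contextual_consummatory": mk((11.80, 3.23), (13.36, 3.27), None),
    }


#: Male fractions used when drawing sex (exact default-cohort counts 10/21,
#: 10/18, 15/17).
MALE_FRACTION = {"melancholic": 10 / 31, "nonmelancholic": 10 / 28, "control": 15 / 32}


def make_affine(grid_shape: tuple[int, int, int], voxel_size_mm: float = 3.0) -> np.ndarray:
    """Diagonal MNI-style affine with the grid centered on the origin."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    aff[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * voxel_size_mm
    return aff


@dataclass
class CohortSpec:
    """Full description of a synthetic study; defaults reproduce the reference
    cohort (31 melancholic / 28 nonmelancholic / 32 control subjects, TR 2.5 s,
    200 volumes, 3 mm grid)."""

    group_sizes: tuple[int, int, int] = (31, 28, 32)  # melancholic, nonmelancholic, control
    grid_shape: tuple[int, int, int] = (24, 28, 22)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.5
    n_volumes: int = 200
    regions: list[RegionSpec] = field(default_factory=default_regions)
    clinical_params: dict = field(default_factory=default_clinical_params)
    nh_score_corr: dict[str, float] = field(
        default_factory=lambda: {"teps_total": -0.5, "teps_contextual_anticipatory": -0.5}
    )
    nh_corr_region: str = "mtg_r"
    nh_corr_group: str = "melancholic"
    noise_sd: float = 1.0
    subject_coupling_sd: float = 0.08
    motion_spike_prob: float = 0.02
    motion_spike_mm: float = 0.3
    motion_drift_mm: float = 0.02
    forced_exclusions: dict[str, int] = field(default_factory=dict)
    n_discard: int = 10  # volumes dropped before measuring the calibration NH
    band_hz: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValueError("three groups with at least 2 subjects each are required")
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed the discard count")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        for score, r in self.nh_score_corr.items():
            if not abs(r) < 1:
                raise ValueError(f"|target correlation| for {score} must be < 1")
        if self.regions and self.nh_corr_region not in {r.label for r in self.regions}:
            logger.warning(
                "coupling region %r not among regions; using %r",
                self.nh_corr_region, self.regions[0].label,
            )
            self.nh_corr_region = self.regions[0].label
        _check_disjoint(self.regions, self.grid_shape)

    @property
    def affine(self) -> np.ndarray:
        return make_affine(self.grid_shape, self.voxel_size_mm)

    def region(self, label: str) -> RegionSpec:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


def _check_disjoint(regions: list[RegionSpec], grid_shape) -> None:
    seen: dict[int, str] = {}
    clashes = set()
    for r in regions:
        if (r.voxels < 0).any() or (r.voxels >= np.asarray(grid_shape)).any():
            raise ValueError(f"region {r.label} extends outside the grid")
        for idx in r.index(tuple(grid_shape)):
            if idx in seen:
                clashes.add((seen[idx], r.label))
            seen[idx] = r.label
    if clashes:
        raise ValueError(f"overlapping regions: {sorted(clashes)}")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    bold: BoldRun
    motion: MotionTrace
    record: dict
    truth: dict[str, float]  # realized per-region coupling


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SyntheticSubject]
    template: np.ndarray       # boolean union of region voxels
    region_labels: np.ndarray  # int parcellation, 0 = background
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    manifest: dict

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([s.record for s in self.subjects])


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def generate_bold(
    region_specs: list[RegionSpec],
    group: str,
    n_volumes: int,
    noise_sd: float,
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int] = (24, 28, 22),
    affine: np.ndarray | None = None,
    tr_s: float = 2.5,
    couplings: dict[str, float] | None = None,
) -> BoldRun:
    """One subject's 4D run under the shared-latent region model.

    ``couplings`` overrides the group coupling per region (used to inject
    per-subject jitter); otherwise each region's group rho is used.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    _check_disjoint(region_specs, grid_shape)
    if affine is None:
        affine = make_affine(grid_shape)
    nx, ny, nz = grid_shape
    data = rng.standard_normal((nx * ny * nz, n_volumes))
    for region in region_specs:
        rho = (couplings or {}).get(region.label, region.coupling_by_group[group])
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"rho for {region.label} must be in [0, 1)")
        latent = rng.standard_normal(n_volumes)
        idx = region.index(grid_shape)
        data[idx] = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * data[idx]
    data *= noise_sd
    return BoldRun(data.reshape(nx, ny, nz, n_volumes).astype(np.float32), affine, tr_s)


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def generate_motion(
    n_volumes: int,
    spike_prob: float,
    spike_mm: float,
    rng: np.random.Generator,
    drift_mm: float = 0.02,
) -> MotionTrace:
    """Slow random-walk drift plus transient single-frame spikes.

    Spikes of ``spike_mm`` land on a random translation axis with probability
    ``spike_prob`` per frame (never on frame 0, the reference).
    """
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must be in [0, 1]")
    params = np.zeros((n_volumes, 6))
    if drift_mm > 0:
        steps = rng.standard_normal((n_volumes, 6))
        steps[:, :3] *= drift_mm
        steps[:, 3:] *= drift_mm / 100.0  # radians; ~0.1-deg-scale cumulative drift
        params = np.cumsum(steps, axis=0)
        params -= params[0]
    if spike_prob > 0 and n_volumes > 1:
        hits = rng.random(n_volumes - 1) < spike_prob
        for frame in np.nonzero(hits)[0] + 1:
            axis = rng.integers(0, 3)
            params[frame, axis] += spike_mm * (1 if rng.random() < 0.5 else -1)
    return MotionTrace(params)


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def _exact_corr_scores(
    nh: np.ndarray, mean: float, sd: float, target_r: float, rng: np.random.Generator
) -> np.ndarray:
    """Scores with sample mean/SD exactly (mean, sd) and sample correlation
    with ``nh`` exactly ``target_r`` (linear-in-NH plus orthogonalized noise)."""
    n = len(nh)
    zx = (nh - nh.mean()) / nh.std(ddof=1)
    e = rng.standard_normal(n)
    e = e - e.mean()
    e = e - (e @ zx) / (zx @ zx) * zx
    ze = e / e.std(ddof=1)
    return mean + sd * (target_r * zx + np.sqrt(1.0 - target_r**2) * ze)


def generate_clinical(
    group: str,
    region_nh: np.ndarray | None,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Score table for one group (one row per subject).

    ``region_nh`` is the group's realized coupling-region NH vector; it drives
    the coupled scores when this is the designated group. Scales a group does
    not take come back as NaN.
    """
    n = spec.group_sizes[GROUPS.index(group)] if group in GROUPS else None
    if region_nh is not None:
        n = len(region_nh)
    if n is None:
        raise KeyError(f"unknown group {group!r}")
    out: dict[str, np.ndarray] = {}
    couple_here = group == spec.nh_corr_group and region_nh is not None and n >= 3
    if couple_here and np.ptp(region_nh) == 0:
        logger.warning("degenerate NH vector; coupled scores fall back to independent draws")
        couple_here = False
    for scale, by_group in spec.clinical_params.items():
        if group not in by_group:
            raise KeyError(f"clinical_params missing group {group!r} for {scale}")
        params = by_group[group]
        if params is None:
            out[scale] = np.full(n, np.nan)
            continue
        mean, sd = params
        if couple_here and scale in spec.nh_score_corr:
            out[scale] = _exact_corr_scores(region_nh, mean, sd, spec.nh_score_corr[scale], rng)
        else:
            out[scale] = mean + sd * rng.standard_normal(n)
    # sex with group-specific male fraction, exact counts
    frac = MALE_FRACTION.get(group, 0.5)
    n_male = int(round(frac * n))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
    out["sex"] = rng.permutation(sex)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# analysis-ready region NH (the quantity clinical coupling is defined on)
# ---------------------------------------------------------------------------

def analysis_ready_region_nh(
    bold: BoldRun,
    region: RegionSpec,
    n_discard: int,
    band_hz: tuple[float, float],
    network_regions: list[RegionSpec] | None = None,
) -> float:
    """Region-mean NH of the discarded/detrended/band-passed series.

    NH is evaluated over the whole network (all ``network_regions``; default
    just the region itself) and averaged within ``region`` — the quantity the
    downstream analysis extracts from a cluster, so the clinical coupling is
    defined on the measured scale.
    """
    regions = network_regions if network_regions else [region]
    idx = np.concatenate([r.index(bold.shape3d) for r in regions])
    series = bold.data.reshape(-1, bold.n_volumes)[idx].T[n_discard:]  # T x m
    series = _detrend_series(series)
    series = _bandpass_series(series, bold.tr_s, *band_hz)
    nh = nh_values(series)
    offsets = np.cumsum([0] + [r.size for r in regions])
    pos = regions.index(region)
    return float(nh[offsets[pos] : offsets[pos + 1]].mean())


def network_nh_from_subject(
    bold: BoldRun,
    motion: MotionTrace,
    spec: CohortSpec,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
) -> dict[str, float]:
    """Per-region mean NH over the whole network after the full temporal
    pipeline (discard, detrend, band-pass, WM/CSF + 24-parameter motion
    regression), evaluated on the network voxels only.

    Because every preprocessing stage acts per voxel, this equals what the
    volumetric pipeline measures on the true network mask; the clinical
    coupling is calibrated against it.
    """
    t_all = bold.n_volumes
    flat = bold.data.reshape(-1, t_all)
    idx = np.concatenate([r.index(bold.shape3d) for r in spec.regions])
    t0 = spec.n_discard

    def prep(rows: np.ndarray) -> np.ndarray:
        s = rows.T[t0:].astype(np.float64)
        return _bandpass_series(_detrend_series(s), bold.tr_s, *spec.band_hz)

    series = prep(flat[idx])
    wm = prep(flat[np.asarray(wm_mask, bool).reshape(-1)]).mean(axis=1)
    csf = prep(flat[np.asarray(csf_mask, bool).reshape(-1)]).mean(axis=1)
    f24 = _bandpass_series(friston24(MotionTrace(motion.params[t0:])), bold.tr_s, *spec.band_hz)
    t = series.shape[0]
    x = np.column_stack([np.ones(t), wm, csf, f24])
    beta, *_ = np.linalg.lstsq(x, series, rcond=None)
    nh = nh_values(series - x @ beta)
    out = {}
    offsets = np.cumsum([0] + [r.size for r in spec.regions])
    for r, a, b in zip(spec.regions, offsets[:-1], offsets[1:]):
        out[r.label] = float(nh[a:b].mean())
    return out


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

def _side_masks(grid_shape) -> tuple[np.ndarray, np.ndarray]:
    wm = np.zeros(grid_shape, dtype=bool)
    csf = np.zeros(grid_shape, dtype=bool)
    wm[0:3, 0:3, 0:3] = True
    csf[-3:, 0:3, 0:3] = True
    return wm, csf


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate the full study; optionally write NIfTI runs, rp-style motion
    files, the subject TSV, template/parcellation volumes and a JSON manifest.

    Same seed, same spec -> identical cohort (bit-reproducible)."""
    ss = np.random.SeedSequence(spec.seed)
    group_streams = {g: np.random.default_rng(s) for g, s in zip(GROUPS, ss.spawn(3))}
    clin_rng = np.random.default_rng(ss.spawn(1)[0])

    subjects: list[SyntheticSubject] = []
    wm, csf = _side_masks(spec.grid_shape)
    per_group: dict[str, list[SyntheticSubject]] = {g: [] for g in GROUPS}
    per_group_nh: dict[str, list[float]] = {g: [] for g in GROUPS}

    counter = 0
    for g, n in zip(GROUPS, spec.group_sizes):
        rng = group_streams[g]
        n_forced = int(spec.forced_exclusions.get(g, 0))
        for i in range(n):
            counter += 1
            sid = f"sub-{counter:03d}"
            couplings = {}
            for region in spec.regions:
                base = region.coupling_by_group[g]
                rho = base + spec.subject_coupling_sd * rng.standard_normal()
                couplings[region.label] = float(np.clip(rho, 0.02, 0.93))
            bold = generate_bold(
                spec.regions, g, spec.n_volumes, spec.noise_sd, rng,
                grid_shape=spec.grid_shape, affine=spec.affine, tr_s=spec.tr_s,
                couplings=couplings,
            )
            motion = generate_motion(
                spec.n_volumes, spec.motion_spike_prob, spec.motion_spike_mm, rng,
                drift_mm=spec.motion_drift_mm,
            )
            if i < n_forced:  # guaranteed to trip the 2 mm rule downstream
                frame = min(spec.n_discard + 5 + i, spec.n_volumes - 1)
                motion.params[frame, 0] += 3.0 * 2.0
            nh_val = network_nh_from_subject(bold, motion, spec, wm, csf)[
                spec.nh_corr_region
            ]
            subj = SyntheticSubject(sid, g, bold, motion, {}, couplings)
            per_group[g].append(subj)
            per_group_nh[g].append(nh_val)

    for g in GROUPS:
        nh_vec = np.asarray(per_group_nh[g])
        scores = generate_clinical(g, nh_vec, spec, clin_rng)
        for row, subj, nh_val in zip(scores.itertuples(index=False), per_group[g], per_group_nh[g]):
            rec = {"subject_id": subj.subject_id, "group": g}
            rec.update(row._asdict())
            rec["coupling_region_nh"] = nh_val
            subj.record = rec
        subjects.extend(per_group[g])

    template = np.zeros(spec.grid_shape, dtype=bool)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for k, region in enumerate(spec.regions, start=1):
        template.reshape(-1)[region.index(spec.grid_shape)] = True
        labels.reshape(-1)[region.index(spec.grid_shape)] = k
    manifest = {
        "seed": spec.seed,
        "group_sizes": dict(zip(GROUPS, spec.group_sizes)),
        "n_subjects": len(subjects),
        "grid_shape": list(spec.grid_shape),
        "tr_s": spec.tr_s,
        "n_volumes": spec.n_volumes,
        "regions": {
            r.label: {"size": int(r.size), "coupling_by_group": r.coupling_by_group}
            for r in spec.regions
        },
        "region_label_ids": {r.label: k for k, r in enumerate(spec.regions, start=1)},
        "nh_score_corr": spec.nh_score_corr,
        "nh_corr_region": spec.nh_corr_region,
        "subjects": [
            {"subject_id": s.subject_id, "group": s.group, "truth": s.truth}
            for s in subjects
        ],
    }
    cohort = Cohort(spec, subjects, template, labels, wm, csf, manifest)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    aff = cohort.spec.affine
    for subj in cohort.subjects:
        img = nib.Nifti1Image(subj.bold.data.astype(np.float32), aff)
        img.header.set_zooms((*subj.bold.voxel_sizes_mm, cohort.spec.tr_s))
        nib.save(img, out_dir / f"{subj.subject_id}_bold.nii.gz")
        np.savetxt(out_dir / f"rp_{subj.subject_id}.txt", subj.motion.params, fmt="%.8e")
    cohort.table.to_csv(out_dir / "subjects.tsv", sep="\t", index=False)
    for name, vol in [
        ("dmn_template", cohort.template.astype(np.uint8)),
        ("region_labels", cohort.region_labels),
        ("wm_mask", cohort.wm_mask.astype(np.uint8)),
        ("csf_mask", cohort.csf_mask.astype(np.uint8)),
    ]:
        nib.save(nib.Nifti1Image(vol, aff), out_dir / f"{name}.nii.gz")
    (out_dir / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2, sort_keys=True))
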