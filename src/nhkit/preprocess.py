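"""Temporal preprocessing of resting-state BOLD runs.

Implements the standard resting-state pipeline applied before network-homogeneity
mapping: discarding initial volumes, motion-based subject exclusion, per-voxel
linear detrending, zero-phase band-pass filtering, and nuisance regression
(white-matter / CSF mean signals plus the Friston 24-parameter motion expansion;
the global mean signal is deliberately *not* regressed out).

Stage order is fixed: discard -> exclusion check -> detrend -> bandpass ->
nuisance regression. Nuisance regressors are band-pass filtered with the same
band before regression so the residuals cannot re-acquire frequencies outside
the pass band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BoldRun",
    "MotionTrace",
    "MotionSummary",
    "ExclusionDecision",
    "PreprocessConfig",
    "discard_initial",
    "motion_exclude",
    "framewise_displacement",
    "detrend_linear",
    "bandpass",
    "friston24",
    "regress_nuisance",
    "preprocess_run",
]

#: Sphere radius (mm) used to convert rotations to arc displacement in FD.
FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class BoldRun:
    """A single subject's 4D BOLD series.

    data : float array, shape (x, y, z, t)
    affine : 4x4 voxel-to-mm map
    tr_s : repetition time in seconds
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 timepoints")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MotionTrace:
    """Rigid-body motion parameters, T x 6.

    Columns: translations tx, ty, tz (mm) then rotations rx, ry, rz (radians),
    the SPM rp-file column convention.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be T x 6, got {self.params.shape}")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass(frozen=True)
class MotionSummary:
    """Per-subject framewise-displacement summary (all in mm)."""

    fd: np.ndarray
    mean_fd: float
    max_abs_translation: float
    max_abs_rotation_deg: float


@dataclass(frozen=True)
class ExclusionDecision:
    keep: bool
    reason: str = ""


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults mirror the conventional resting-state settings: drop the first
    10 volumes, band-pass 0.01-0.08 Hz, exclude subjects moving more than
    2 mm translation or 2 degrees rotation."""

    n_discard: int = 10
    band_hz: tuple[float, float] = (0.01, 0.08)
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    regress_wm: bool = True
    regress_csf: bool = True
    regress_friston24: bool = True
    regress_global: bool = False  # global signal preserved by design

    def validate(self, tr_s: float) -> None:
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * tr_s)
        if not (0.0 < low < high < nyquist):
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < low < high < Nyquist={nyquist:g}"
            )


# ---------------------------------------------------------------------------
# volume discard
# ---------------------------------------------------------------------------

def discard_initial(run: BoldRun, motion: MotionTrace, n: int) -> tuple[BoldRun, MotionTrace]:
    """Drop the first ``n`` frames from the run and its motion trace together."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= run.n_volumes:
        raise ValueError(f"cannot discard {n} of {run.n_volumes} volumes")
    if motion.n_frames != run.n_volumes:
        raise ValueError("motion trace and run must have the same frame count")
    if n == 0:
        return run, motion
    return (
        replace(run, data=run.data[..., n:]),
        MotionTrace(motion.params[n:]),
    )


# ---------------------------------------------------------------------------
# motion QC
# ---------------------------------------------------------------------------

def motion_exclude(motion: MotionTrace, config: PreprocessConfig) -> ExclusionDecision:
    """Exclude a subject whose displacement from the first retained frame
    exceeds the translation threshold on any axis, or whose rotation exceeds
    the angular threshold (strict inequality at the threshold itself)."""
    if motion.n_frames == 0:
        raise ValueError("empty motion trace")
    ref = motion.params[0]
    disp = motion.params - ref
    trans = np.abs(disp[:, :3])                      # mm
    rot_deg = np.degrees(np.abs(disp[:, 3:]))        # radians -> degrees
    axes = ["x", "y", "z"]
    if trans.max() > config.max_translation_mm:
        frame, axis = np.unravel_index(np.argmax(trans), trans.shape)
        return ExclusionDecision(
            False,
            f"translation {trans[frame, axis]:.3f} mm on {axes[axis]} at frame "
            f"{frame} exceeds {config.max_translation_mm} mm",
        )
    if rot_deg.max() > config.max_rotation_deg:
        frame, axis = np.unravel_index(np.argmax(rot_deg), rot_deg.shape)
        return ExclusionDecision(
            False,
            f"rotation {rot_deg[frame, axis]:.3f} deg about {axes[axis]} at frame "
            f"{frame} exceeds {config.max_rotation_deg} deg",
        )
    return ExclusionDecision(True)


def framewise_displacement(motion: MotionTrace) -> MotionSummary:
    """Power-style FD: sum of absolute frame-to-frame changes over the six
    parameters, rotations converted to arc length on a 50 mm sphere.
    The first frame's FD is 0 by convention."""
    if motion.n_frames < 2:
        raise ValueError("FD needs at least 2 frames")
    d = np.diff(motion.params, axis=0)
    fd_body = np.abs(d[:, :3]).sum(axis=1) + FD_ROTATION_RADIUS_MM * np.abs(d[:, 3:]).sum(axis=1)
    fd = np.concatenate([[0.0], fd_body])
    ref = motion.params[0]
    disp = motion.params - ref
    return MotionSummary(
        fd=fd,
        mean_fd=float(fd.mean()),
        max_abs_translation=float(np.abs(disp[:, :3]).max()),
        max_abs_rotation_deg=float(np.degrees(np.abs(disp[:, 3:])).max()),
    )


# ---------------------------------------------------------------------------
# detrend / bandpass
# ---------------------------------------------------------------------------

def _detrend_series(series_2d: np.ndarray) -> np.ndarray:
    """Remove per-column least-squares line (intercept + slope). series_2d is T x K."""
    t = series_2d.shape[0]
    x = np.column_stack([np.ones(t), np.arange(t, dtype=np.float64)])
    beta, *_ = np.linalg.lstsq(x, series_2d, rcond=None)
    return series_2d - x @ beta


def detrend_linear(run: BoldRun) -> BoldRun:
    """Remove each voxel's least-squares linear trend (and mean)."""
    if run.n_volumes < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    flat = run.data.reshape(-1, run.n_volumes).T  # T x V
    out = _detrend_series(flat).T.reshape(run.data.shape)
    return replace(run, data=out)


def _bandpass_series(series_2d: np.ndarray, tr_s: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Ideal (hard-edged) frequency-domain band-pass, zero phase. T x K in/out.

    Frequencies f with low <= f <= high are retained; DC and everything else
    is zeroed.
    """
    t = series_2d.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(series_2d, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=0)


def bandpass(run: BoldRun, low_hz: float | None = None, high_hz: float | None = None) -> BoldRun:
    """Zero-phase FFT band-pass filter (default 0.01-0.08 Hz)."""
    cfg = PreprocessConfig()
    if low_hz is None:
        low_hz = cfg.band_hz[0]
    if high_hz is None:
        high_hz = cfg.band_hz[1]
    nyquist = 1.0 / (2.0 * run.tr_s)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(f"band ({low_hz}, {high_hz}) outside (0, Nyquist={nyquist:g})")
    flat = run.data.reshape(-1, run.n_volumes).T
    out = _bandpass_series(flat, run.tr_s, low_hz, high_hz).T.reshape(run.data.shape)
    return replace(run, data=out)


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

def friston24(motion: MotionTrace) -> np.ndarray:
    """Friston 24-parameter expansion: the 6 parameters, the same lagged by one
    frame (first row zero), and the squares of both sets. T x 24."""
    p = motion.params
    lagged = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.column_stack([p, lagged, p**2, lagged**2])


def _prune_collinear(design: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, list[int]]:
    """Greedy rank-revealing prune: keep columns in order, drop any column that
    lies in the span of those already kept."""
    kept: list[int] = []
    basis = np.zeros((design.shape[0], 0))
    for j in range(design.shape[1]):
        col = design[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col
        norm = np.linalg.norm(resid)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            kept.append(j)
            basis = np.column_stack([basis, resid / norm])
    dropped = [j for j in range(design.shape[1]) if j not in kept]
    return design[:, kept], dropped


def regress_nuisance(
    run: BoldRun,
    motion: MotionTrace | None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    config: PreprocessConfig | None = None,
    filter_regressors: bool = True,
) -> BoldRun:
    """Per-voxel OLS residualization against mean WM signal, mean CSF signal
    and the Friston-24 motion expansion (plus an intercept).

    Regressors are band-pass filtered with the run's analysis band first (see
    module docstring). Collinear columns are dropped with a logged warning.
    The global mean signal is never included.
    """
    config = config or PreprocessConfig()
    t = run.n_volumes
    flat = run.data.reshape(-1, t)  # V x T
    cols: list[np.ndarray] = []

    def mean_signal(mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != run.shape3d:
            raise ValueError("mask grid does not match run")
        if not mask.any():
            raise ValueError("empty nuisance mask")
        return flat[mask.reshape(-1)].mean(axis=0)

    if config.regress_wm and wm_mask is not None:
        cols.append(mean_signal(wm_mask))
    if config.regress_csf and csf_mask is not None:
        cols.append(mean_signal(csf_mask))
    if config.regress_friston24 and motion is not None:
        if motion.n_frames != t:
            raise ValueError("motion trace frame count does not match run")
        cols.extend(friston24(motion).T)
    if not cols:
        return run

    x = np.column_stack(cols)
    if filter_regressors:
        x = _bandpass_series(x, run.tr_s, *config.band_hz)
    x = np.column_stack([np.ones(t), x])
    x, dropped = _prune_collinear(x)
    if dropped:
        logger.warning("nuisance design rank-deficient; dropped columns %s", dropped)
        warnings.warn(f"dropped {len(dropped)} collinear nuisance columns", stacklevel=2)
    beta, *_ = np.linalg.lstsq(x, flat.T, rcond=None)
    resid = flat.T - x @ beta
    return replace(run, data=resid.T.reshape(run.data.shape))


# ---------------------------------------------------------------------------
# orchestrated per-subject preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    run: BoldRun | None
    motion: MotionTrace | None
    summary: MotionSummary
    decision: ExclusionDecision


def preprocess_run(
    run: BoldRun,
    motion: MotionTrace,
    config: PreprocessConfig | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
) -> PreprocessResult:
    """Full per-subject temporal pipeline; returns ``run=None`` for excluded
    subjects. FD is computed on the retained (post-discard) frames."""
    config = config or PreprocessConfig()
    config.validate(run.tr_s)
    run, motion = discard_initial(run, motion, config.n_discard)
    decision = motion_exclude(motion, config)
    summary = framewise_displacement(motion)
    if not decision.keep:
        return PreprocessResult(None, None, summary, decision)
    run = detrend_linear(run)
    run = bandpass(run, *config.band_hz)
    run = regress_nuisance(run, motion, wm_mask, csf_mask, config)
    if np.isnan(run.data).any():
        raise FloatingPointError("NaN produced during preprocessing")
    return PreprocessResult(run, motion, summary, decision)
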