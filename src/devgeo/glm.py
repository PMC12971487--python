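"""First-level GLM with motion spike censoring and dispersion-based voxel QC.

The design matrix carries one regressor of interest per condition (event
boxcars convolved with the canonical double-gamma Glover HRF), one spike
regressor per high-motion frame (framewise displacement above 1.5 mm by
default, which removes that frame from parameter estimation), six motion
parameters, a linear trend, a cosine drift basis below a 0.01 Hz high-pass
cutoff and an intercept. Runs with more than half their frames censored
are rejected. Per voxel, estimator dispersion — the condition rows of
diag((X'X)^-1) times the voxel residual mean square — flags unstable fits;
voxels whose dispersion exceeds 10 are excluded from pattern analysis.
Condition estimates are run-level mean centered per voxel before any
similarity computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import glover_hrf

from devgeo.cohort import MotionTrace

FWD_THRESHOLD_MM = 1.5
MAX_CENSORED_FRACTION = 0.5
DISPERSION_MAX = 10.0
HIGHPASS_HZ = 0.01


@dataclass
class QCReport:
    """Per-run motion quality control summary."""

    n_frames: int
    n_censored: int
    accepted: bool
    median_fwd: float

    @property
    def censored_fraction(self) -> float:
        return self.n_censored / self.n_frames


@dataclass
class DesignMatrix:
    """Frames-by-regressors design with column role bookkeeping."""

    matrix: np.ndarray
    roles: list[str]  # per column: condition | spike | motion | trend | cosine | intercept
    names: list[str]
    tr: float

    @property
    def condition_columns(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "condition"])

    @property
    def n_spikes(self) -> int:
        return sum(r == "spike" for r in self.roles)


@dataclass
class BetaPatterns:
    """Condition-by-voxel response estimates for one run.

    ``dispersion`` is the per-voxel estimator-variance proxy (max over
    condition regressors of the design-covariance diagonal times the voxel
    residual mean square); ``valid`` masks voxels retained for pattern
    analysis.
    """

    subject_id: str
    run_id: int
    betas: np.ndarray  # n_conditions x n_voxels
    dispersion: np.ndarray  # n_voxels
    valid: np.ndarray  # n_voxels bool
    mean_centered: bool = False
    condition_dispersion: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_conditions(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]


def censor_and_qc(
    motion: MotionTrace,
    fwd_threshold: float = FWD_THRESHOLD_MM,
    max_censored_fraction: float = MAX_CENSORED_FRACTION,
) -> tuple[QCReport, np.ndarray]:
    """Flag high-motion frames and decide run acceptance.

    Frames with FWD strictly above ``fwd_threshold`` are censored; the run
    is rejected when the censored fraction exceeds
    ``max_censored_fraction``.
    """
    if fwd_threshold <= 0:
        raise ValueError("fwd_threshold must be positive")
    mask = motion.fwd > fwd_threshold
    frac = mask.mean()
    report = QCReport(
        n_frames=motion.n_frames,
        n_censored=int(mask.sum()),
        accepted=bool(frac <= max_censored_fraction),
        median_fwd=motion.median,
    )
    return report, mask


def hrf_convolved_regressors(
    run_events: pd.DataFrame,
    n_conditions: int,
    tr: float,
    n_frames: int,
    hrf_params: dict | None = None,
    oversampling: int = 16,
) -> np.ndarray:
    """Condition regressors: event boxcars convolved with the Glover HRF.

    Boxcars are built on an oversampled grid, convolved with the
    double-gamma HRF (peak ~6 s, undershoot ~16 s, ratio 1/6 — the
    canonical defaults), then sampled at frame acquisition times.
    """
    hrf_params = hrf_params or {}
    dt = tr / oversampling
    n_hi = n_frames * oversampling
    hrf = glover_hrf(tr, oversampling=oversampling, time_length=32.0, **hrf_params)
    x = np.zeros((n_frames, n_conditions))
    t_hi = np.arange(n_hi) * dt
    for cond in range(n_conditions):
        sel = run_events[run_events["condition"] == cond]
        if len(sel) == 0:
            continue
        box = np.zeros(n_hi)
        for onset, dur in zip(sel["onset"], sel["duration"]):
            box[(t_hi >= onset) & (t_hi < onset + dur)] += 1.0
        conv = np.convolve(box, hrf)[:n_hi]
        x[:, cond] = conv[::oversampling]
    return x


def cosine_drift_basis(tr: float, n_frames: int, highpass_hz: float) -> np.ndarray:
    """Unit-norm DCT-II drift regressors with frequencies below the
    high-pass cutoff (the standard cosine drift model)."""
    t = np.arange(n_frames)
    order = int(np.floor(2 * n_frames * tr * highpass_hz))
    cols = []
    for k in range(1, order + 1):
        c = np.cos(np.pi * k * (2 * t + 1) / (2 * n_frames))
        cols.append(c * np.sqrt(2.0 / n_frames))
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)


def build_design_matrix(
    events,
    tr: float | None = None,
    n_frames: int | None = None,
    run: int = 0,
    motion_params: np.ndarray | None = None,
    censor_mask: np.ndarray | None = None,
    n_conditions: int | None = None,
    hrf_params: dict | None = None,
    highpass_hz: float = HIGHPASS_HZ,
) -> DesignMatrix:
    """Assemble the first-level design for one run.

    ``events`` is an EventTable or a per-run events DataFrame. Columns:
    one HRF-convolved regressor per condition, one spike column (single 1)
    per censored frame, six motion covariates when provided, a linear
    trend, the cosine drift set and an intercept.
    """
    if hasattr(events, "for_run"):
        tr = events.tr if tr is None else tr
        n_frames = events.n_frames if n_frames is None else n_frames
        run_events = events.for_run(run)
    else:
        run_events = events
        if tr is None or n_frames is None:
            raise ValueError("tr and n_frames required with a raw events frame")
    if (run_events["onset"] + run_events["duration"]).max() > n_frames * tr:
        raise ValueError("events extend beyond the run duration")
    if n_conditions is None:
        n_conditions = int(run_events["condition"].max()) + 1

    cols = [hrf_convolved_regressors(run_events, n_conditions, tr, n_frames, hrf_params)]
    roles = ["condition"] * n_conditions
    names = [f"cond_{i:02d}" for i in range(n_conditions)]

    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.size != n_frames:
            raise ValueError("censor mask length must equal n_frames")
        idx = np.flatnonzero(censor_mask)
        spikes = np.zeros((n_frames, idx.size))
        spikes[idx, np.arange(idx.size)] = 1.0
        cols.append(spikes)
        roles += ["spike"] * idx.size
        names += [f"spike_f{f}" for f in idx]

    if motion_params is not None:
        motion_params = np.asarray(motion_params, dtype=float)
        if motion_params.shape[0] != n_frames:
            raise ValueError("motion parameter rows must equal n_frames")
        cols.append(motion_params)
        roles += ["motion"] * motion_params.shape[1]
        names += [f"motion_{i}" for i in range(motion_params.shape[1])]

    trend = np.linspace(-1.0, 1.0, n_frames)[:, None]
    cols.append(trend)
    roles.append("trend")
    names.append("trend")

    cosines = cosine_drift_basis(tr, n_frames, highpass_hz)
    if cosines.shape[1]:
        cols.append(cosines)
        roles += ["cosine"] * cosines.shape[1]
        names += [f"cosine_{k + 1}" for k in range(cosines.shape[1])]

    cols.append(np.ones((n_frames, 1)))
    roles.append("intercept")
    names.append("intercept")

    return DesignMatrix(matrix=np.column_stack(cols), roles=roles, names=names, tr=tr)


def fit_glm(
    timeseries: np.ndarray,
    design: DesignMatrix,
    subject_id: str = "",
    run_id: int = 0,
) -> BetaPatterns:
    """Ordinary least squares per voxel.

    Per voxel v and condition c, dispersion_cv = [(X'X)^-1]_cc * RMS_v,
    with the residual degrees of freedom reduced by the spike-column count
    (censored frames carry no information about the conditions). The
    per-voxel dispersion summary is the maximum over condition regressors.
    """
    x = design.matrix
    y = np.asarray(timeseries, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != x.shape[0]:
        raise ValueError("timeseries frames must match design rows")

    # Collinearity check via pivoted QR.
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag[0] * max(x.shape) * np.finfo(float).eps).sum())
    if rank < x.shape[1]:
        bad = sorted(design.names[j] for j in piv[rank:])
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {', '.join(bad)}"
        )

    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = x.shape[0] - x.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    rms = (resid**2).sum(axis=0) / dof

    xtx_inv = np.linalg.inv(x.T @ x)
    cond_idx = design.condition_columns
    var_diag = np.diag(xtx_inv)[cond_idx]  # per condition regressor
    cond_dispersion = var_diag[:, None] * rms[None, :]
    dispersion = cond_dispersion.max(axis=0)

    return BetaPatterns(
        subject_id=subject_id,
        run_id=run_id,
        betas=beta[cond_idx],
        dispersion=dispersion,
        valid=np.ones(y.shape[1], dtype=bool),
        condition_dispersion=cond_dispersion,
    )


def filter_voxels_by_dispersion(
    betas: BetaPatterns, max_dispersion: float = DISPERSION_MAX
) -> tuple[BetaPatterns, float]:
    """Invalidate voxels whose dispersion exceeds the threshold.

    Returns the updated patterns and the newly excluded proportion.
    """
    bad = betas.dispersion > max_dispersion
    valid = betas.valid & ~bad
    excluded = float(bad.mean())
    return (
        BetaPatterns(
            subject_id=betas.subject_id,
            run_id=betas.run_id,
            betas=betas.betas,
            dispersion=betas.dispersion,
            valid=valid,
            mean_centered=betas.mean_centered,
            condition_dispersion=betas.condition_dispersion,
        ),
        excluded,
    )


def mean_center_runs(betas: BetaPatterns) -> BetaPatterns:
    """Subtract each voxel's run-level mean across conditions.

    Controls for baseline signal differences between runs; idempotent.
    """
    if betas.n_conditions < 2:
        raise ValueError("mean centering requires >= 2 conditions")
    centered = betas.betas - betas.betas.mean(axis=0, keepdims=True)
    return BetaPatterns(
        subject_id=betas.subject_id,
        run_id=betas.run_id,
        betas=centered,
        dispersion=betas.dispersion,
        valid=betas.valid,
        mean_centered=True,
        condition_dispersion=betas.condition_dispersion,
    )


def compute_tsnr(
    timeseries: np.ndarray,
    roi_mask: np.ndarray | None = None,
    detrend: bool = True,
) -> tuple[float, int]:
    """Temporal signal-to-noise ratio averaged over ROI voxels.

    Per voxel: temporal mean divided by the temporal standard deviation of
    the (optionally linearly detrended) timecourse. Zero-variance voxels
    are excluded; their count is returned alongside the ROI mean. The
    detrended standard deviation removes slow scanner drift that would
    otherwise deflate tSNR.
    """
    y = np.asarray(timeseries, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] < 2:
        raise ValueError("tSNR needs at least 2 frames")
    if roi_mask is not None:
        y = y[:, np.asarray(roi_mask, dtype=bool)]
    mean = y.mean(axis=0)
    if detrend:
        t = np.linspace(-1.0, 1.0, y.shape[0])
        x = np.column_stack([t, np.ones_like(t)])
        resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        sd = resid.std(axis=0, ddof=2)
    else:
        sd = y.std(axis=0, ddof=1)
    ok = sd > 1e-10 * np.maximum(np.abs(mean), 1.0)
    if not ok.any():
        raise ValueError("all ROI voxels have zero temporal variance")
    return float(np.mean(mean[ok] / sd[ok])), int((~ok).sum())
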