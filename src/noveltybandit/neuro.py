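"""Prediction-error-modulated fMRI design matrices, censoring, and GLM.

Six task event classes are modelled: cue and feedback phases on explore and
non-explore trials, plus stimulus/feedback presentation on no-response
trials.  Cue-phase regressors carry an EV parametric modulator and
feedback-phase regressors an RPE modulator; modulators are mean-centered
per run before convolution so the modulated column is orthogonal to its
unmodulated companion.  Volumes whose volume-to-volume motion (Euclidean
norm over the six motion parameters) exceeds 0.5 mm are censored together
with their predecessor; subjects with more than 15% censored volumes are
excluded.  The GLM is ordinary least squares on censored-row-deleted data
expressed in percent signal change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_fit import Trajectory
from .novelty import ExploreLabels
from .task_env import ChoiceDataset

__all__ = [
    "CensorMask",
    "DesignMatrix",
    "EVENT_CLASSES",
    "build_design",
    "build_events",
    "censor_mask",
    "double_gamma_hrf",
    "fit_glm",
    "percent_signal_change",
    "subject_qc",
]

EVENT_CLASSES = (
    "cue_nonexplore",
    "cue_explore",
    "feedback_nonexplore",
    "feedback_explore",
    "cue_noresponse",
    "feedback_noresponse",
)
MODULATED_CLASSES = (
    "cue_nonexplore",
    "cue_explore",
    "feedback_nonexplore",
    "feedback_explore",
)

CENSOR_THRESHOLD_MM = 0.5
MAX_CENSOR_FRACTION = 0.15


@dataclass
class CensorMask:
    """Per-volume keep flags and the censored fraction."""

    keep: np.ndarray

    @property
    def fraction_censored(self) -> float:
        return float(1.0 - self.keep.mean())

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())


@dataclass
class DesignMatrix:
    """Volumes x regressors design with named columns.

    ``modulated_columns`` names the EV/RPE amplitude-modulated regressors
    whose betas are the downstream quantities of interest.
    """

    matrix: pd.DataFrame
    tr: float
    run_of_volume: np.ndarray
    modulated_columns: list[str] = field(default_factory=list)
    dropped_classes: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalized to 1.

    Positive gamma peaking near ``peak_delay`` seconds minus a ``ratio``
    scaled undershoot gamma peaking near ``undershoot_delay`` seconds.
    """
    t = np.asarray(t, dtype=float)
    pos = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    neg = stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = pos - ratio * neg
    peak = h.max()
    return h / peak if peak > 0 else h


def build_events(
    dataset: ChoiceDataset,
    trajectory: Trajectory,
    labels: ExploreLabels,
    seed: int,
    cue_duration: float = 1.5,
    feedback_duration: float = 1.5,
    jitter_range: tuple[float, float] = (1.0, 2.0),
) -> pd.DataFrame:
    """Event table (onset, duration, trial_type, modulator, run) for a session.

    Trial timing follows the task structure: cue window, jittered interval,
    feedback window, second jittered interval.  Cue events are modulated by
    the chosen stimulus's pre-choice EV and feedback events by the trial
    RPE; no-response trials contribute unmodulated events.  Onsets restart
    at zero at each run boundary.
    """
    rng = np.random.default_rng(seed)
    rows = []
    runs = dataset.schedule.run_of_trial
    t_clock = 0.0
    prev_run = runs[0] if len(runs) else 0
    for t in range(dataset.n_trials):
        if runs[t] != prev_run:
            t_clock = 0.0
            prev_run = runs[t]
        j1, j2 = rng.uniform(*jitter_range, size=2)
        cue_onset = t_clock
        fb_onset = cue_onset + cue_duration + j1
        if dataset.responded[t]:
            suffix = "explore" if labels.explore[t] else "nonexplore"
            rows.append((cue_onset, cue_duration, f"cue_{suffix}", trajectory.ev_chosen[t], runs[t]))
            rows.append((fb_onset, feedback_duration, f"feedback_{suffix}", trajectory.rpe[t], runs[t]))
        else:
            rows.append((cue_onset, cue_duration, "cue_noresponse", np.nan, runs[t]))
            rows.append((fb_onset, feedback_duration, "feedback_noresponse", np.nan, runs[t]))
        t_clock = fb_onset + feedback_duration + j2
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "modulator", "run"])


def _convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    tr: float,
    n_volumes: int,
    run_length: int,
    hrf_kwargs: dict,
    oversample: int = 16,
) -> np.ndarray:
    """Amplitude-weighted boxcar convolved with the HRF, sampled at the TR."""
    dt = tr / oversample
    n_fine = run_length * oversample
    stick = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        if i0 >= n_fine:
            continue
        stick[i0 : min(i1, n_fine)] += amp
    hrf_t = np.arange(0, 32.0, dt)
    h = double_gamma_hrf(hrf_t, **hrf_kwargs)
    conv = np.convolve(stick, h)[:n_fine]
    return conv[::oversample]


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_volumes: int,
    motion: np.ndarray | None = None,
    drift_degree: int = 1,
    hrf_kwargs: dict | None = None,
    run_of_volume: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the task GLM design matrix.

    One unmodulated regressor per event class present, plus a
    run-mean-centered modulated companion for each of the four EV/RPE
    classes, plus six motion regressors when supplied and per-run
    polynomial drift terms.  Event classes with no events are dropped (and
    recorded in ``dropped_classes``).  Events outside the scan are
    rejected.
    """
    hrf_kwargs = hrf_kwargs or {}
    if run_of_volume is None:
        run_of_volume = np.zeros(n_volumes, dtype=int)
    run_of_volume = np.asarray(run_of_volume)
    if "run" not in events.columns:
        events = events.assign(run=0)

    run_ids = sorted(np.unique(run_of_volume))
    run_len = {r: int((run_of_volume == r).sum()) for r in run_ids}
    for r in sorted(events["run"].unique()):
        if r not in run_len:
            raise ValueError(f"events reference run {r} absent from run_of_volume")
        dur_s = run_len[r] * tr
        ev_r = events[events["run"] == r]
        if (ev_r["onset"] + ev_r["duration"]).max() > dur_s + tr:
            raise ValueError(f"run {r}: events extend beyond the scan duration")

    columns: dict[str, np.ndarray] = {}
    modulated, dropped = [], []

    def per_run_column(ev: pd.DataFrame, amps_fn) -> np.ndarray:
        col = np.zeros(n_volumes)
        for r in run_ids:
            sel = ev["run"] == r
            if not sel.any():
                continue
            sub = ev[sel]
            seg = _convolve_events(
                sub["onset"].to_numpy(float),
                sub["duration"].to_numpy(float),
                amps_fn(sub),
                tr,
                n_volumes,
                run_len[r],
                hrf_kwargs,
            )
            col[run_of_volume == r] = seg
        return col

    for cls in EVENT_CLASSES:
        ev = events[events["trial_type"] == cls]
        if ev.empty:
            dropped.append(cls)
            continue
        columns[cls] = per_run_column(ev, lambda sub: np.ones(len(sub)))
        if cls in MODULATED_CLASSES:
            def centered(sub: pd.DataFrame) -> np.ndarray:
                m = sub["modulator"].to_numpy(float)
                if not np.all(np.isfinite(m)):
                    raise ValueError(f"missing modulator on a {cls} event")
                return m - m.mean()

            mod_col = per_run_column(ev, centered)
            name = f"{cls}_mod"
            if np.allclose(mod_col, 0.0):
                dropped.append(name)
            else:
                columns[name] = mod_col
                modulated.append(name)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_volumes, 6):
            raise ValueError(f"motion must be (n_volumes, 6), got {motion.shape}")
        for j in range(6):
            columns[f"motion{j}"] = motion[:, j]

    for r in run_ids:
        in_run = run_of_volume == r
        t_norm = np.linspace(-1, 1, run_len[r])
        for d in range(drift_degree + 1):
            col = np.zeros(n_volumes)
            col[in_run] = t_norm**d
            columns[f"drift_run{r}_deg{d}"] = col

    frame = pd.DataFrame(columns)
    keep = [c for c in frame.columns if not np.allclose(frame[c].to_numpy(), 0.0)]
    dropped += [c for c in frame.columns if c not in keep]
    return DesignMatrix(
        matrix=frame[keep],
        tr=tr,
        run_of_volume=run_of_volume,
        modulated_columns=[c for c in modulated if c in keep],
        dropped_classes=dropped,
    )


def censor_mask(motion_params: np.ndarray, threshold_mm: float = CENSOR_THRESHOLD_MM) -> CensorMask:
    """Censor volumes (and predecessors) with motion norm above threshold.

    The per-volume displacement is the Euclidean norm of the backward
    difference of the six motion parameters (rotations supplied in
    mm-equivalent units); the first volume has zero displacement.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion parameters must be (n_volumes, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need >= 2 volumes")
    norm = np.zeros(motion.shape[0])
    norm[1:] = np.linalg.norm(np.diff(motion, axis=0), axis=1)
    trigger = norm > threshold_mm
    censor = trigger.copy()
    censor[:-1] |= trigger[1:]  # predecessor of every triggering volume
    return CensorMask(keep=~censor)


def subject_qc(mask: CensorMask, max_fraction: float = MAX_CENSOR_FRACTION) -> bool:
    """Movement inclusion rule: keep unless censored fraction exceeds 15%.

    Exactly 15% is included (strict inequality, with float tolerance).
    """
    return mask.fraction_censored <= max_fraction + 1e-12


def percent_signal_change(timeseries: np.ndarray, mask: CensorMask | None = None) -> np.ndarray:
    """Re-express each voxel series as percent change from its mean.

    The mean is taken over uncensored volumes when a mask is given.
    Zero-mean voxels are flagged with a warning and returned as NaN.
    """
    y = np.asarray(timeseries, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    keep = mask.keep if mask is not None else np.ones(y.shape[0], dtype=bool)
    mean = y[keep].mean(axis=0)
    out = np.full_like(y, np.nan)
    ok = mean != 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-mean voxel(s) flagged as missing", stacklevel=2)
    out[:, ok] = 100.0 * (y[:, ok] - mean[ok]) / mean[ok]
    return out[:, 0] if squeeze else out


@dataclass
class GLMResult:
    """Per-voxel OLS estimates; rows of ``betas``/``tstats`` follow design columns."""

    betas: pd.DataFrame
    tstats: pd.DataFrame
    df_resid: int
    modulated_columns: list[str]


def fit_glm(bold: np.ndarray, design: DesignMatrix, mask: CensorMask | None = None) -> GLMResult:
    """Ordinary least squares per voxel on censored-row-deleted data.

    Raises on rank deficiency, naming the collinear columns.  The betas of
    the EV/RPE-modulated columns are the quantities carried into group
    analysis.
    """
    Y = np.asarray(bold, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix.to_numpy(float)
    names = list(design.matrix.columns)
    keep = mask.keep if mask is not None else np.ones(X.shape[0], dtype=bool)
    Xk, Yk = X[keep], Y[keep]
    if Xk.shape[0] <= Xk.shape[1]:
        raise ValueError("fewer kept volumes than regressors")
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        _, R = np.linalg.qr(Xk)
        suspect = [names[j] for j in range(len(names)) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {suspect}")
    coef, _, _, _ = np.linalg.lstsq(Xk, Yk, rcond=None)
    resid = Yk - Xk @ coef
    df = Xk.shape[0] - Xk.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv_diag = np.diag(np.linalg.inv(Xk.T @ Xk))
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = coef / se
    return GLMResult(
        betas=pd.DataFrame(coef, index=names),
        tstats=pd.DataFrame(tstats, index=names),
        df_resid=df,
        modulated_columns=design.modulated_columns,
    )
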