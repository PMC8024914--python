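"""Maximum-likelihood estimation of the delta-rule/softmax model.

Estimation follows the group-learning-rate workflow: a pooled fit shares
the learning rate alpha across subjects (inverse temperature beta shared or
per subject), and downstream EV/RPE trajectories are then derived at the
fixed group alpha.  Trajectories depend only on alpha and the feedback
history, never on beta, which enters the likelihood alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .agent import EV_INIT_NOVEL_DEFAULT, AgentParams
from .task_env import ChoiceDataset

__all__ = [
    "FitResult",
    "Trajectory",
    "derive_trajectory",
    "fit_pooled",
    "fit_subject",
    "model_fit_diagnostics",
    "negative_log_likelihood",
]

ALPHA_BOUNDS = (0.01, 1.0)
BETA_BOUNDS = (0.0, 50.0)

#: Offered stimuli with lag <= this count as "novel" (the explore window).
NOVEL_LAG_MAX = 2


class DataIntegrityError(ValueError):
    """Raised when choice data contradict the schedule."""


class NonConvergenceError(RuntimeError):
    """Raised when every optimizer restart fails."""


@dataclass
class Trajectory:
    """Per-trial EVs and prediction errors for one subject at fixed alpha.

    ``ev_offered[t, k]`` is the pre-choice EV of the slot-``k`` stimulus on
    trial ``t``; ``rpe[t] = feedback[t] - ev_chosen[t]`` on responded trials
    and NaN otherwise.  ``ev_best_nonnovel[t]`` is the maximum pre-choice EV
    among offered non-novel stimuli (lag > ``novel_lag_max``), NaN when all
    three offered stimuli are novel.
    """

    alpha: float
    ev_init: float
    novel_lag_max: int
    ev_offered: np.ndarray
    ev_chosen: np.ndarray
    rpe: np.ndarray
    lag: np.ndarray
    is_novel: np.ndarray
    ev_best_nonnovel: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.ev_offered.shape[0]


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``fixed`` names parameters held at given values during optimization.
    ``beta_by_subject`` is populated by pooled fits with per-subject beta.
    ``identifiable`` is False when the profiled likelihood is flat in a
    nominally free parameter (e.g. alpha under beta = 0).
    """

    alpha_hat: float
    beta_hat: float
    nll: float
    n_trials: int
    converged: bool
    n_restarts_used: int = 1
    fixed: dict = field(default_factory=dict)
    identifiable: bool = True
    beta_by_subject: np.ndarray | None = None


def derive_trajectory(
    dataset: ChoiceDataset,
    alpha: float,
    ev_init: float = EV_INIT_NOVEL_DEFAULT,
    ev_init_start: float | None = None,
    novel_lag_max: int = NOVEL_LAG_MAX,
) -> Trajectory:
    """Deterministic forward pass establishing EVs and RPEs on each trial.

    Only the chosen stimulus updates (delta rule); non-responded trials
    leave all EVs unchanged and yield a missing RPE.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if ev_init_start is None:
        ev_init_start = ev_init
    sched = dataset.schedule
    offered = sched.offered
    n = offered.shape[0]
    lag = sched.lags()
    chosen_id = dataset.chosen_id
    responded = dataset.responded
    feedback = dataset.feedback

    ev: dict[int, float] = {}
    ev_offered = np.empty((n, 3))
    ev_chosen = np.full(n, np.nan)
    rpe = np.full(n, np.nan)
    for t in range(n):
        row = offered[t]
        for k in range(3):
            sid = row[k]
            if sid not in ev:
                ev[sid] = ev_init_start if sid < 3 else ev_init
            ev_offered[t, k] = ev[sid]
        if responded[t]:
            cid = chosen_id[t]
            hits = np.flatnonzero(row == cid)
            if hits.size == 0:
                raise DataIntegrityError(
                    f"trial {t}: chosen stimulus {cid} not among offered {row.tolist()}"
                )
            k = int(hits[0])
            ev_chosen[t] = ev_offered[t, k]
            rpe[t] = feedback[t] - ev_chosen[t]
            ev[cid] = ev_chosen[t] + alpha * rpe[t]

    is_novel = lag <= novel_lag_max
    masked = np.where(is_novel, -np.inf, ev_offered)
    ev_best = masked.max(axis=1)
    ev_best[~np.isfinite(ev_best)] = np.nan
    return Trajectory(
        alpha=alpha,
        ev_init=ev_init,
        novel_lag_max=novel_lag_max,
        ev_offered=ev_offered,
        ev_chosen=ev_chosen,
        rpe=rpe,
        lag=lag,
        is_novel=is_novel,
        ev_best_nonnovel=ev_best,
    )


def _nll_given_evs(
    ev_offered: np.ndarray, chosen_slot: np.ndarray, responded: np.ndarray, beta: float
) -> float:
    """Softmax negative log-likelihood over responded trials (log-sum-exp safe)."""
    z = beta * ev_offered[responded]
    ll = z[np.arange(z.shape[0]), chosen_slot[responded]] - logsumexp(z, axis=1)
    out = -float(ll.sum())
    if not np.isfinite(out):
        raise FloatingPointError("non-finite likelihood")
    return out


def negative_log_likelihood(dataset: ChoiceDataset, params: AgentParams) -> float:
    """Negative log-likelihood of the realized choices under ``params``.

    EVs come from :func:`derive_trajectory` at ``params.alpha``; choice
    probabilities from the softmax at ``params.beta``.  Non-responded
    trials are excluded.
    """
    if int(dataset.responded.sum()) < 1:
        raise ValueError("need at least one responded trial")
    traj = derive_trajectory(
        dataset, params.alpha, ev_init=params.ev_init_novel, ev_init_start=params.ev_init_start
    )
    return _nll_given_evs(traj.ev_offered, dataset.chosen_slot, dataset.responded, params.beta)


def _optimize_beta(
    ev_offered: np.ndarray, chosen_slot: np.ndarray, responded: np.ndarray
) -> tuple[float, float]:
    """1-D bounded minimization of the nll over beta at fixed EVs."""
    res = minimize_scalar(
        lambda b: _nll_given_evs(ev_offered, chosen_slot, responded, b),
        bounds=BETA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), float(res.fun)


def fit_subject(
    dataset: ChoiceDataset,
    fixed: dict | None = None,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
    beta_bounds: tuple[float, float] = BETA_BOUNDS,
    n_restarts: int = 9,
    ev_init: float = EV_INIT_NOVEL_DEFAULT,
) -> FitResult:
    """Maximum-likelihood fit of (alpha, beta) for one subject.

    Multi-start bounded L-BFGS-B from a fixed grid of initial points;
    ``fixed`` may pin either parameter (e.g. ``{"beta": 0.0}``).  Flags
    non-identifiability when the profiled likelihood is flat in alpha.
    """
    fixed = dict(fixed or {})
    chosen_ids = np.unique(dataset.chosen_id[dataset.responded])
    if chosen_ids.size < 2:
        raise ValueError("degenerate dataset: fewer than 2 distinct chosen stimuli")
    chosen_slot, responded = dataset.chosen_slot, dataset.responded
    n_resp = int(responded.sum())

    ev_cache: dict[float, np.ndarray] = {}

    def evs_at(alpha: float) -> np.ndarray:
        key = round(float(alpha), 12)
        if key not in ev_cache:
            ev_cache[key] = derive_trajectory(dataset, key, ev_init=ev_init).ev_offered
        return ev_cache[key]

    def objective(theta: np.ndarray) -> float:
        if "alpha" in fixed:
            alpha, rest = fixed["alpha"], theta
        else:
            alpha, rest = theta[0], theta[1:]
        beta = fixed["beta"] if "beta" in fixed else rest[0]
        return _nll_given_evs(evs_at(alpha), chosen_slot, responded, beta)

    free: list[tuple[str, tuple[float, float]]] = []
    if "alpha" not in fixed:
        free.append(("alpha", alpha_bounds))
    if "beta" not in fixed:
        free.append(("beta", beta_bounds))

    if not free:
        nll = objective(np.empty(0))
        return FitResult(fixed["alpha"], fixed["beta"], nll, n_resp, True, 0, fixed)

    alpha_grid = [0.2, 0.5, 0.8]
    beta_grid = [1.0, 5.0, 20.0]
    starts = []
    for a in alpha_grid if "alpha" not in fixed else [None]:
        for b in beta_grid if "beta" not in fixed else [None]:
            starts.append([v for v in (a, b) if v is not None])
    starts = starts[:n_restarts]

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            res = minimize(
                objective,
                np.asarray(x0, dtype=float),
                method="L-BFGS-B",
                bounds=[b for _, b in free],
            )
        except FloatingPointError:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise NonConvergenceError(f"all {n_used} restarts failed for {dataset.subject_id}")

    values = dict(zip((name for name, _ in free), np.atleast_1d(best.x)))
    alpha_hat = float(fixed.get("alpha", values.get("alpha", np.nan)))
    beta_hat = float(fixed.get("beta", values.get("beta", np.nan)))

    identifiable = True
    if "alpha" not in fixed:
        # Flat-likelihood probe: if the nll barely moves across the alpha
        # range at the fitted beta, alpha is not identified (e.g. beta ~ 0).
        probe = [
            _nll_given_evs(evs_at(a), chosen_slot, responded, beta_hat)
            for a in np.linspace(alpha_bounds[0], alpha_bounds[1], 7)
        ]
        identifiable = (max(probe) - min(probe)) > 1e-6 * max(1.0, abs(best.fun))

    return FitResult(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        nll=float(best.fun),
        n_trials=n_resp,
        converged=bool(best.success),
        n_restarts_used=n_used,
        fixed=fixed,
        identifiable=identifiable,
    )


def fit_pooled(
    datasets: list[ChoiceDataset],
    share: str = "alpha",
    ev_init: float = EV_INIT_NOVEL_DEFAULT,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
) -> FitResult:
    """Pooled fit with the learning rate shared across subjects.

    ``share='alpha'`` estimates one alpha and a free beta per subject;
    ``share='alpha_beta'`` shares both.  Implemented as a profile
    likelihood: for each candidate alpha the trajectories are derived once
    and beta is concentrated out by 1-D bounded minimization (jointly or
    per subject).  This mirrors the group-learning-rate procedure used to
    fix alpha for downstream RPE regressors.
    """
    if len(datasets) < 2:
        raise ValueError("pooled fit needs >= 2 datasets")
    if share not in {"alpha", "alpha_beta"}:
        raise ValueError("share must be 'alpha' or 'alpha_beta'")

    slots = [d.chosen_slot for d in datasets]
    resps = [d.responded for d in datasets]
    n_resp = int(sum(r.sum() for r in resps))

    def profile(alpha: float) -> tuple[float, float | np.ndarray]:
        evs = [derive_trajectory(d, alpha, ev_init=ev_init).ev_offered for d in datasets]
        if share == "alpha_beta":
            ev_all = np.concatenate([e[r] for e, r in zip(evs, resps)])
            slot_all = np.concatenate([s[r] for s, r in zip(slots, resps)])
            beta, nll = _optimize_beta(ev_all, slot_all, np.ones(ev_all.shape[0], dtype=bool))
            return nll, beta
        betas, nll = [], 0.0
        for e, s, r in zip(evs, slots, resps):
            b, f = _optimize_beta(e, s, r)
            betas.append(b)
            nll += f
        return nll, np.asarray(betas)

    res = minimize_scalar(
        lambda a: profile(a)[0],
        bounds=alpha_bounds,
        method="bounded",
        options={"xatol": 1e-5},
    )
    alpha_hat = float(res.x)
    nll, beta = profile(alpha_hat)

    if share == "alpha_beta":
        return FitResult(alpha_hat, float(beta), float(nll), n_resp, bool(res.success))
    return FitResult(
        alpha_hat=alpha_hat,
        beta_hat=float(np.mean(beta)),
        nll=float(nll),
        n_trials=n_resp,
        converged=bool(res.success),
        beta_by_subject=np.asarray(beta),
    )


def model_fit_diagnostics(cohort: pd.DataFrame) -> dict:
    """Consistency-of-fit regressions for model-predicted choice proportions.

    Expects subject-level columns ``predicted`` and ``observed`` (proportion
    of best non-novel choices) and, optionally, standardized ``audit``,
    ``cudit`` and ``sex``.  Returns the prediction-observation Pearson r and
    an OLS of observed on predicted plus clinical scores and their
    prediction interactions, which checks that model fit quality does not
    vary across the symptom distribution.
    """
    if len(cohort) < 10:
        raise ValueError("need >= 10 subjects")
    pred = cohort["predicted"].to_numpy(float)
    obs = cohort["observed"].to_numpy(float)
    if np.std(pred) == 0:
        raise ValueError("degenerate input: zero-variance predictions")
    r = float(np.corrcoef(pred, obs)[0, 1])

    X = pd.DataFrame({"predicted": pred})
    for col in ("sex", "audit", "cudit"):
        if col in cohort:
            X[col] = cohort[col].to_numpy(float)
    for col in ("audit", "cudit"):
        if col in cohort:
            X[f"{col}_x_predicted"] = X[col] * pred
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.OLS(obs, sm.add_constant(X)).fit()
    return {
        "r": r,
        "coefficients": model.params.to_dict(),
        "pvalues": model.pvalues.to_dict(),
        "n": len(cohort),
    }
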