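"""Explore-trial labelling and novelty-propensity (NP) estimation.

A trial is an "explore" trial when the subject chose a stimulus exactly two
trials after its introduction (lag 2) — the point in the session where
novelty-driven choice peaks.  Novelty propensity is the value of the best
non-novel alternative, EV_best, at which a subject is 50% likely to choose
the novel stimulus on such trials; it is read off a per-subject logistic
regression of novel choice on EV_best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .model_fit import Trajectory
from .task_env import ChoiceDataset

__all__ = [
    "ExploreLabels",
    "InsufficientDataError",
    "NoveltyResult",
    "estimate_np",
    "estimate_np_pooled",
    "label_explore",
    "novel_choice_by_lag",
]

EXPLORE_LAG = 2
MIN_LAG2_TRIALS = 8

#: Divergence threshold on the logistic slope used to flag separation.
_SEPARATION_SLOPE = 1e3

#: Plausibility window for the 50% point (dollars): the EV support [0, 0.30]
#: padded by half the reward magnitude on each side.  A shallow logistic can
#: place its midpoint far outside the observable range; such extrapolations
#: carry no usable subject information and are flagged non-identifiable.
NP_WINDOW = (-0.15, 0.45)


class InsufficientDataError(ValueError):
    """Raised when too few lag-2 trials exist to estimate NP."""


@dataclass
class ExploreLabels:
    """Boolean explore flag per trial (True only on responded lag-2 choices)."""

    explore: np.ndarray

    @property
    def n_explore(self) -> int:
        return int(self.explore.sum())


@dataclass
class NoveltyResult:
    """Logistic 50%-point estimate of novelty propensity.

    ``np_value = -intercept / slope`` (dollars) when the fit is
    identifiable: a converged logistic model with a negative slope (higher
    best non-novel EV makes novel choice less likely) and no separation.
    Otherwise ``np_value`` is NaN and ``identifiable`` is False.
    """

    np_value: float
    intercept: float
    slope: float
    n_lag2_trials: int
    identifiable: bool


def label_explore(trajectory: Trajectory, dataset: ChoiceDataset) -> ExploreLabels:
    """Flag responded trials whose chosen stimulus has lag == 2."""
    lag = trajectory.lag
    resp = dataset.responded
    chosen_lag = np.full(dataset.n_trials, -1)
    idx = np.flatnonzero(resp)
    chosen_lag[idx] = lag[idx, dataset.chosen_slot[idx]]
    return ExploreLabels(explore=(chosen_lag == EXPLORE_LAG))


def novel_choice_by_lag(
    datasets: list[ChoiceDataset], return_counts: bool = False
) -> dict[int, float] | tuple[dict[int, float], dict[int, int]]:
    """Proportion of offers chosen as a function of lag since introduction.

    For each lag value, the fraction of (trial, offered stimulus) pairs at
    that lag on which the stimulus was chosen, pooled over datasets.  Lags
    never offered are absent from the result (not reported as zero).  With
    ``return_counts`` the per-lag offer counts are returned as well.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    offers: dict[int, int] = {}
    picks: dict[int, int] = {}
    for ds in datasets:
        lag = ds.schedule.lags()
        resp = ds.responded
        for t in np.flatnonzero(resp):
            k_chosen = ds.chosen_slot[t]
            for k in range(3):
                ell = int(lag[t, k])
                offers[ell] = offers.get(ell, 0) + 1
                if k == k_chosen:
                    picks[ell] = picks.get(ell, 0) + 1
    props = {ell: picks.get(ell, 0) / n for ell, n in sorted(offers.items())}
    if return_counts:
        return props, dict(sorted(offers.items()))
    return props


def _lag2_trials(
    trajectory: Trajectory, dataset: ChoiceDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome/predictor pairs for the NP logistic.

    Restricted to responded trials where some offered stimulus has lag == 2
    and at least one non-novel alternative exists; outcome = 1 when the
    lag-2 stimulus was chosen, predictor = EV of the best non-novel
    offered stimulus.
    """
    lag = trajectory.lag
    has_lag2 = (lag == EXPLORE_LAG).any(axis=1)
    ok = dataset.responded & has_lag2 & np.isfinite(trajectory.ev_best_nonnovel)
    idx = np.flatnonzero(ok)
    chose_lag2 = lag[idx, dataset.chosen_slot[idx]] == EXPLORE_LAG
    return chose_lag2.astype(float), trajectory.ev_best_nonnovel[idx]


def estimate_np(trajectory: Trajectory, dataset: ChoiceDataset) -> NoveltyResult:
    """Estimate the EV_best at which P(choose novel | lag-2 trial) = 0.5.

    Maximum-likelihood logistic regression with intercept.  Reports
    non-identifiability (rather than extrapolating) when the outcome or
    predictor is constant, the slope is non-negative, or separation makes
    the slope diverge.
    """
    y, x = _lag2_trials(trajectory, dataset)
    n = y.size
    if n < MIN_LAG2_TRIALS:
        raise InsufficientDataError(
            f"only {n} usable lag-2 trials (< {MIN_LAG2_TRIALS}) for {dataset.subject_id}"
        )
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return NoveltyResult(np.nan, np.nan, np.nan, n, identifiable=False)

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception:
            return NoveltyResult(np.nan, np.nan, np.nan, n, identifiable=False)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    separated = abs(slope) > _SEPARATION_SLOPE or not np.isfinite(slope)
    if separated or slope >= 0:
        return NoveltyResult(np.nan, intercept, slope, n, identifiable=False)
    np_value = -intercept / slope
    if not NP_WINDOW[0] <= np_value <= NP_WINDOW[1]:
        return NoveltyResult(np.nan, intercept, slope, n, identifiable=False)
    return NoveltyResult(np_value, intercept, slope, n, identifiable=True)


def estimate_np_pooled(
    pairs: list[tuple[Trajectory, ChoiceDataset]]
) -> NoveltyResult:
    """Cohort-level novelty propensity: one logistic over all lag-2 trials.

    Pools the (novel chosen, EV_best) pairs of every subject into a single
    logistic fit — a lower-variance companion to the per-subject
    :func:`estimate_np` when only a group-level 50% point is needed.
    """
    ys, xs = [], []
    for traj, ds in pairs:
        y, x = _lag2_trials(traj, ds)
        ys.append(y)
        xs.append(x)
    y = np.concatenate(ys)
    x = np.concatenate(xs)
    if y.size < MIN_LAG2_TRIALS:
        raise InsufficientDataError(f"only {y.size} pooled lag-2 trials")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return NoveltyResult(np.nan, np.nan, np.nan, int(y.size), identifiable=False)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    if abs(slope) > _SEPARATION_SLOPE or not np.isfinite(slope) or slope >= 0:
        return NoveltyResult(np.nan, intercept, slope, int(y.size), identifiable=False)
    return NoveltyResult(-intercept / slope, intercept, slope, int(y.size), identifiable=True)
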