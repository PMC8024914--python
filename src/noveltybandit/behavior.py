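"""Subject-level behavioral metrics and their clinical correlations.

The headline behavioral metric is the proportion of trials on which the
subject chose the offered non-novel stimulus with the highest learned EV
("best non-novel"); it indexes exploitation quality.  Metrics feed partial
correlations (controlling for sex) with alcohol/cannabis symptom scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import clinstats
from .model_fit import Trajectory
from .task_env import ChoiceDataset

__all__ = ["behavioral_correlations", "prop_best_nonnovel", "total_winnings"]


def prop_best_nonnovel(
    trajectory: Trajectory, dataset: ChoiceDataset, use_true_ev: bool = False
) -> tuple[float, int]:
    """Fraction of eligible trials where the best non-novel stimulus was chosen.

    A stimulus is non-novel once its lag exceeds the trajectory's novelty
    window (default lag >= 3).  Trials offering no non-novel stimulus are
    excluded from the denominator; returns ``(proportion, n_eligible)`` and
    ``(nan, 0)`` with a warning when no trial is eligible.  With
    ``use_true_ev`` the latent expected payoffs replace the learned EVs
    (simulation diagnostics only).
    """
    if use_true_ev:
        rates = dataset.schedule.stimuli
        values = np.array(
            [[rates[s].expected_payoff for s in row] for row in dataset.schedule.offered]
        )
    else:
        values = trajectory.ev_offered
    nonnovel = ~trajectory.is_novel
    eligible = dataset.responded & nonnovel.any(axis=1)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        warnings.warn("no eligible trials for prop_best_nonnovel", stacklevel=2)
        return float("nan"), 0
    masked = np.where(nonnovel[idx], values[idx], -np.inf)
    best_slot = masked.argmax(axis=1)
    # ties broken toward the chosen slot: chosen counts as best if its value
    # equals the maximum among non-novel offers
    chosen = dataset.chosen_slot[idx]
    chosen_val = np.where(
        nonnovel[idx, chosen], values[idx, chosen], -np.inf
    )
    hit = chosen_val >= masked[np.arange(idx.size), best_slot]
    return float(hit.mean()), int(idx.size)


def total_winnings(dataset: ChoiceDataset, payout_fraction: float | None = None) -> tuple[float, float]:
    """Total dollar winnings and the fraction actually paid out."""
    if payout_fraction is None:
        payout_fraction = dataset.schedule.config.payout_fraction
    winnings = dataset.total_winnings
    return winnings, payout_fraction * winnings


def behavioral_correlations(
    cohort: pd.DataFrame,
    score_cols: tuple[str, ...] = ("audit_rankit_z", "cudit_z"),
    metric_cols: tuple[str, ...] = ("prop_best_nonnovel", "np_value"),
    control_cols: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Partial correlations of clinical scores with behavioral metrics.

    Controls for the columns in ``control_cols`` (sex by default) via
    :func:`noveltybandit.clinstats.partial_correlation`; subjects with any
    missing value in a pair are dropped pairwise.  Returns a tidy frame
    with columns score, metric, r, df, p, n.
    """
    if len(cohort) < 10:
        raise ValueError("need >= 10 subjects")
    rows = []
    for score in score_cols:
        for metric in metric_cols:
            cols = [score, metric, *control_cols]
            sub = cohort[cols].dropna()
            x = sub[score].to_numpy(float)
            y = sub[metric].to_numpy(float)
            z = sub[list(control_cols)].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"degenerate input: constant column in ({score}, {metric})")
            r, df, p = clinstats.partial_correlation(x, y, z)
            rows.append({"score": score, "metric": metric, "r": r, "df": df, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
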