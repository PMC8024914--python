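"""Delta-rule / softmax reinforcement-learning agent for the novelty task.

The agent tracks an expected value EV per active stimulus, chooses among the
three offered stimuli by softmax with inverse temperature beta, and updates
only the chosen stimulus's EV by the delta rule

    RPE = F - EV,    EV <- EV + alpha * RPE,

where F is the dollar feedback and alpha the learning rate.  Newly
introduced (novel) stimuli start at an initial EV reflecting the cohort's
novelty propensity (default $0.216).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .task_env import ChoiceDataset, TaskSchedule

__all__ = ["AgentParams", "choice_probabilities", "simulate_agent", "update_value"]

#: Default initial expected value assigned to novel stimuli (dollars); the
#: group-average novelty propensity used as the novelty prior.
EV_INIT_NOVEL_DEFAULT = 0.216


@dataclass(frozen=True)
class AgentParams:
    """Learning rate, softmax inverse temperature, and EV initialization.

    ``ev_init_novel`` applies to novel introductions; ``ev_init_start`` to
    the three stimuli present on trial 0 (both default to the novelty prior).
    """

    alpha: float
    beta: float
    ev_init_novel: float = EV_INIT_NOVEL_DEFAULT
    ev_init_start: float = EV_INIT_NOVEL_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0 <= self.ev_init_novel <= 0.30:
            raise ValueError("ev_init_novel must lie in [0, 0.30]")


def choice_probabilities(evs: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities over the offered stimuli.

    P(i) = exp(beta * EV_i) / sum_j exp(beta * EV_j); computed with a
    max-shift so large beta cannot overflow.  Translation-invariant in the
    EVs; beta = 0 gives the uniform policy.
    """
    evs = np.asarray(evs, dtype=float)
    if not np.all(np.isfinite(evs)):
        raise ValueError("EVs must be finite")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = beta * evs
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def update_value(ev: float, feedback: float, alpha: float) -> tuple[float, float]:
    """One delta-rule update; returns ``(new_ev, rpe)``.

    ``rpe = feedback - ev`` and ``new_ev = ev + alpha * rpe``.  Only the
    chosen stimulus's value is ever passed through this update.
    """
    if not (math.isfinite(ev) and math.isfinite(feedback) and math.isfinite(alpha)):
        raise ValueError("inputs must be finite")
    rpe = feedback - ev
    return ev + alpha * rpe, rpe


def simulate_agent(
    schedule: TaskSchedule,
    params: AgentParams,
    seed: int,
    subject_id: str = "sim",
) -> ChoiceDataset:
    """Play one session of ``schedule`` with a softmax/delta-rule agent.

    Choices are sampled from :func:`choice_probabilities` of the current
    EVs; feedback is drawn from the task's Bernoulli payoff scheme; the
    chosen stimulus's EV is then updated.  Reproducible given
    ``(schedule, params, seed)``.  The simulator always responds; the data
    model's ``responded`` flag exists for observed data with omissions.
    """
    rng = np.random.default_rng(seed)
    offered = schedule.offered
    n_trials = offered.shape[0]
    rates = np.array([schedule.stimuli[s].payoff_rate for s in range(len(schedule.stimuli))])
    magnitude = schedule.config.reward_magnitude

    ev: dict[int, float] = {}
    chosen_slot = np.empty(n_trials, dtype=int)
    feedback = np.empty(n_trials, dtype=float)
    prob_chosen = np.empty(n_trials, dtype=float)
    beta = params.beta

    for t in range(n_trials):
        row = offered[t]
        for sid in row:
            if sid not in ev:
                ev[sid] = params.ev_init_start if sid < 3 else params.ev_init_novel
        evs = np.array([ev[sid] for sid in row])
        probs = choice_probabilities(evs, beta)
        k = int(rng.choice(3, p=probs))
        sid = int(row[k])
        f = magnitude if rng.random() < rates[sid] else 0.0
        ev[sid], _ = update_value(ev[sid], f, params.alpha)
        chosen_slot[t] = k
        feedback[t] = f
        prob_chosen[t] = probs[k]

    return ChoiceDataset(
        subject_id=subject_id,
        schedule=schedule,
        chosen_slot=chosen_slot,
        feedback=feedback,
        responded=np.ones(n_trials, dtype=bool),
        prob_chosen=prob_chosen,
    )
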