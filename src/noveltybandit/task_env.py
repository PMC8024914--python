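"""Novelty-task environment: schedules, payoffs, and feedback sampling.

The task is a three-armed bandit in which every stimulus carries a hidden
payoff probability and stays on screen for a limited number of consecutive
trials before being replaced by a novel stimulus.  A session starts with
three initial stimuli and introduces a fixed number of novel stimuli
(default 40, split evenly across two scanner runs); each stimulus lives for
a uniformly drawn 5-9 consecutive trials.  Winning feedback is a fixed
dollar amount delivered with the stimulus's payoff probability, so expected
payoffs span $0.00-$0.30.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChoiceDataset",
    "InvalidConfigError",
    "ScheduleError",
    "StimulusSpec",
    "TaskConfig",
    "TaskSchedule",
    "bernoulli_feedback",
    "compute_lags",
    "generate_schedule",
    "sample_feedback",
]


class InvalidConfigError(ValueError):
    """Raised when a task configuration violates its constraints."""


class ScheduleError(ValueError):
    """Raised when a schedule is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class StimulusSpec:
    """One bandit arm: identity, payoff probability, and introduction trial.

    ``expected_payoff`` is ``reward_magnitude * payoff_rate`` in dollars and
    lies in [0, reward_magnitude].  ``introduced_at`` is the 0-based index of
    the first trial on which the stimulus is offered.
    """

    stimulus_id: int
    payoff_rate: float
    expected_payoff: float
    introduced_at: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.payoff_rate <= 1.0:
            raise ValueError(f"payoff_rate must be in [0, 1], got {self.payoff_rate}")
        if self.introduced_at < 0:
            raise ValueError("introduced_at must be >= 0")


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters.

    Defaults reproduce the standard session: two runs, 40 novel-stimulus
    introductions in total, stimulus lifetimes uniform on {5..9} trials,
    $0.30 winning feedback, and a 10% payout of total winnings.
    """

    n_runs: int = 2
    n_novel_introductions: int = 40
    lifetime_min: int = 5
    lifetime_max: int = 9
    reward_magnitude: float = 0.30
    payout_fraction: float = 0.10
    n_slots: int = 3

    def __post_init__(self) -> None:
        if self.lifetime_min < 1:
            raise InvalidConfigError("lifetime_min must be >= 1")
        if self.lifetime_min > self.lifetime_max:
            raise InvalidConfigError("lifetime_min must be <= lifetime_max")
        if self.n_novel_introductions < 1:
            raise InvalidConfigError("n_novel_introductions must be >= 1")
        if not 0 < self.payout_fraction <= 1:
            raise InvalidConfigError("payout_fraction must be in (0, 1]")
        if self.n_slots != 3:
            raise InvalidConfigError("the task is a three-armed bandit: n_slots must be 3")
        if self.n_runs < 1:
            raise InvalidConfigError("n_runs must be >= 1")


@dataclass
class TaskSchedule:
    """A fully resolved session plan.

    Attributes
    ----------
    config, seed
        Provenance: the generating configuration and RNG seed.
    stimuli
        Mapping from stimulus id to :class:`StimulusSpec`.  Ids 0..2 are the
        initial stimuli; higher ids are novel introductions in order.
    lifetimes
        Realized consecutive-trial count per stimulus id; every lifetime lies
        within ``[lifetime_min, lifetime_max]``.
    offered
        ``(n_trials, 3)`` int array, the stimulus offered in each slot stream.
    positions
        ``(n_trials, 3)`` int array: ``positions[t, k]`` is the screen
        location (0=left, 1=mid, 2=right) of slot ``k`` on trial ``t``;
        randomization metadata only.
    run_of_trial
        ``(n_trials,)`` int array of run indices.
    stream_ids
        Per slot, the ordered stimulus ids that occupied it.  The trailing
        stimuli of each stream may have end-of-session-aligned lifetimes
        (see :func:`generate_schedule`).
    """

    config: TaskConfig
    seed: int
    stimuli: dict[int, StimulusSpec]
    lifetimes: dict[int, int]
    offered: np.ndarray
    positions: np.ndarray
    run_of_trial: np.ndarray
    stream_ids: list[list[int]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.offered.shape[0]

    @property
    def n_novel(self) -> int:
        return len(self.stimuli) - self.config.n_slots

    def lags(self) -> np.ndarray:
        """Per-trial, per-slot lag (1 on a stimulus's first offered trial)."""
        if not hasattr(self, "_lag_cache"):
            self._lag_cache = compute_lags(self)
        return self._lag_cache

    def trials_frame(self) -> pd.DataFrame:
        """Trial table with slot-ordered and position-ordered stimulus ids."""
        lag = self.lags()
        n = self.n_trials
        by_pos = np.empty_like(self.offered)
        rows = np.arange(n)[:, None]
        by_pos[rows, self.positions] = self.offered
        return pd.DataFrame(
            {
                "run": self.run_of_trial,
                "trial": np.arange(n),
                "stim_left": by_pos[:, 0],
                "stim_mid": by_pos[:, 1],
                "stim_right": by_pos[:, 2],
                "lag_slot0": lag[:, 0],
                "lag_slot1": lag[:, 1],
                "lag_slot2": lag[:, 2],
            }
        )


@dataclass
class ChoiceDataset:
    """One subject's trial-by-trial choices on a schedule.

    ``chosen_slot`` holds the slot index (0-2) of the chosen stimulus per
    trial, or -1 on non-response trials.  ``feedback`` is the dollar outcome
    (NaN when not responded).  ``prob_chosen`` optionally records the model
    probability of each realized choice (simulation diagnostics).
    """

    subject_id: str
    schedule: TaskSchedule
    chosen_slot: np.ndarray
    feedback: np.ndarray
    responded: np.ndarray
    prob_chosen: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.schedule.n_trials
        for name in ("chosen_slot", "feedback", "responded"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ScheduleError(f"{name} length {arr.shape[0]} != n_trials {n}")
        bad = self.responded & ~np.isfinite(self.feedback)
        if bad.any():
            raise ScheduleError("feedback must be present on every responded trial")
        if (~self.responded & (self.chosen_slot >= 0)).any():
            raise ScheduleError("chosen stimulus recorded on a non-responded trial")

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials

    @property
    def chosen_id(self) -> np.ndarray:
        """Chosen stimulus id per trial (-1 when not responded)."""
        out = np.full(self.n_trials, -1, dtype=int)
        resp = self.responded
        out[resp] = self.schedule.offered[resp, self.chosen_slot[resp]]
        return out

    @property
    def total_winnings(self) -> float:
        return float(np.nansum(np.where(self.responded, self.feedback, 0.0)))

    def to_frame(self) -> pd.DataFrame:
        sched = self.schedule
        lag = sched.lags()
        resp = self.responded
        lag_chosen = np.where(resp, lag[np.arange(self.n_trials), self.chosen_slot], -1)
        frame = sched.trials_frame()[["run", "trial", "stim_left", "stim_mid", "stim_right"]].copy()
        frame.insert(0, "subject_id", self.subject_id)
        frame["chosen"] = np.where(resp, self.chosen_id, -1)
        frame["feedback"] = self.feedback
        frame["responded"] = resp.astype(int)
        frame["lag_chosen"] = lag_chosen
        if self.prob_chosen is not None:
            frame["prob_chosen"] = self.prob_chosen
        return frame


FeedbackScheme = Callable[[StimulusSpec, np.random.Generator], float]


def bernoulli_feedback(magnitude: float) -> FeedbackScheme:
    """Default feedback scheme: win ``magnitude`` dollars w.p. ``payoff_rate``."""

    def scheme(stimulus: StimulusSpec, rng: np.random.Generator) -> float:
        return magnitude if rng.random() < stimulus.payoff_rate else 0.0

    return scheme


def sample_feedback(
    stimulus: StimulusSpec,
    rng: np.random.Generator,
    scheme: FeedbackScheme | None = None,
    reward_magnitude: float = 0.30,
) -> float:
    """Draw one trial's dollar feedback for ``stimulus``."""
    if not 0.0 <= stimulus.payoff_rate <= 1.0:
        raise ValueError("payoff_rate outside [0, 1]")
    if scheme is None:
        scheme = bernoulli_feedback(reward_magnitude)
    return scheme(stimulus, rng)


def _equalize_streams(
    stream_ids: list[list[int]],
    lifetimes: dict[int, int],
    lifetime_min: int,
    lifetime_max: int,
) -> None:
    """Align the slot streams so the session ends on a full trial.

    Lifetimes are drawn independently, so the three slot streams generally
    end ragged once the novel-stimulus queue is exhausted.  The session
    length is set to the median stream span, and the trailing lifetimes of
    the other two streams are adjusted toward it (latest stimulus first,
    clamped to ``[lifetime_min, lifetime_max]``).  The two adjustments have
    opposite signs, so they are mean-zero across seeds and touch only the
    tail of each stream, leaving interior lifetimes exactly iid uniform;
    every stimulus — including the last one introduced — completes its
    (aligned) lifetime on the final trial of the session.
    """
    totals = [sum(lifetimes[s] for s in ids) for ids in stream_ids]
    target = int(np.median(totals))
    for k, ids in enumerate(stream_ids):
        delta = target - sum(lifetimes[s] for s in ids)
        for sid in reversed(ids):
            if delta == 0:
                break
            if delta > 0:
                take = min(lifetime_max - lifetimes[sid], delta)
            else:
                take = max(lifetime_min - lifetimes[sid], delta)
            lifetimes[sid] += take
            delta -= take
        if delta:
            raise ScheduleError(
                "cannot align slot streams: lifetime range too tight for "
                f"{len(lifetimes)} stimuli (residual {delta} trials)"
            )


def generate_schedule(config: TaskConfig, seed: int) -> TaskSchedule:
    """Generate a reproducible session schedule.

    The three initial stimuli occupy the slots on trial 0.  Whenever a
    stimulus's lifetime elapses, the next queued novel stimulus replaces it
    (simultaneous expiries are served lowest-id first).  The trial count is
    emergent: the session ends when the last introduced stimulus expires.
    Payoff rates are independent Uniform(0, 1) draws per stimulus, so
    expected payoffs are Uniform(0, reward_magnitude).
    """
    rng = np.random.default_rng(seed)
    n_slots = config.n_slots
    n_total = n_slots + config.n_novel_introductions

    drawn = rng.integers(config.lifetime_min, config.lifetime_max + 1, size=n_total)
    payoff_rates = rng.random(n_total)
    lifetimes = {sid: int(drawn[sid]) for sid in range(n_total)}

    # Greedy stream assignment: the next novel stimulus joins whichever slot
    # stream expires first (ties by lowest expiring stimulus id).
    stream_ids: list[list[int]] = [[k] for k in range(n_slots)]
    stream_end = [lifetimes[k] for k in range(n_slots)]
    for sid in range(n_slots, n_total):
        k = min(range(n_slots), key=lambda j: (stream_end[j], stream_ids[j][-1]))
        stream_ids[k].append(sid)
        stream_end[k] += lifetimes[sid]

    _equalize_streams(stream_ids, lifetimes, config.lifetime_min, config.lifetime_max)
    n_trials = sum(lifetimes[s] for s in stream_ids[0])

    offered = np.empty((n_trials, n_slots), dtype=int)
    introduced_at = {}
    for k, ids in enumerate(stream_ids):
        t = 0
        for sid in ids:
            introduced_at[sid] = t
            offered[t : t + lifetimes[sid], k] = sid
            t += lifetimes[sid]
        if t != n_trials:
            raise ScheduleError("slot streams misaligned after equalization")

    stimuli = {
        sid: StimulusSpec(
            stimulus_id=sid,
            payoff_rate=float(payoff_rates[sid]),
            expected_payoff=float(payoff_rates[sid] * config.reward_magnitude),
            introduced_at=introduced_at[sid],
        )
        for sid in range(n_total)
    }

    # Run boundaries: introductions are split evenly across runs; a run
    # starts on the introduction trial of its first novel stimulus.
    per_run = -(-config.n_novel_introductions // config.n_runs)  # ceil
    run_of_trial = np.zeros(n_trials, dtype=int)
    for r in range(1, config.n_runs):
        first_sid = n_slots + r * per_run
        if first_sid < n_total:
            run_of_trial[introduced_at[first_sid] :] = r

    positions = np.argsort(rng.random((n_trials, n_slots)), axis=1)

    return TaskSchedule(
        config=config,
        seed=seed,
        stimuli=stimuli,
        lifetimes=lifetimes,
        offered=offered,
        positions=positions,
        run_of_trial=run_of_trial,
        stream_ids=stream_ids,
    )


def compute_lags(schedule: TaskSchedule) -> np.ndarray:
    """Lag table: trials since introduction (1 on first offer) per slot.

    Raises :class:`ScheduleError` if a stimulus is offered before its
    recorded introduction trial.
    """
    offered = schedule.offered
    n_trials, n_slots = offered.shape
    lag = np.empty_like(offered)
    for t in range(n_trials):
        for k in range(n_slots):
            sid = offered[t, k]
            intro = schedule.stimuli[sid].introduced_at
            if t < intro:
                raise ScheduleError(
                    f"stimulus {sid} offered on trial {t} before introduction {intro}"
                )
            lag[t, k] = t - intro + 1
    return lag


def with_payoff_rates(schedule: TaskSchedule, rates: Sequence[float]) -> TaskSchedule:
    """Return a copy of ``schedule`` with replaced payoff rates (diagnostics)."""
    if len(rates) != len(schedule.stimuli):
        raise ScheduleError("one payoff rate per stimulus required")
    mag = schedule.config.reward_magnitude
    stimuli = {
        sid: replace(spec, payoff_rate=float(rates[sid]), expected_payoff=float(rates[sid]) * mag)
        for sid, spec in schedule.stimuli.items()
    }
    return replace_schedule(schedule, stimuli=stimuli)


def replace_schedule(schedule: TaskSchedule, **kwargs) -> TaskSchedule:
    return replace(schedule, **kwargs)
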