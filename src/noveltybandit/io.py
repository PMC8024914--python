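"""On-disk formats: choice TSV, events TSV, motion text, clinical CSV, YAML.

All tables are plain text with explicit schemas.  Readers validate rather
than coerce: missing columns, bad dtypes, unordered trials, or a chosen
stimulus outside the offered set are rejected with row-numbered errors.
Missing values are written as ``.``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task_env import ChoiceDataset, StimulusSpec, TaskConfig, TaskSchedule

__all__ = [
    "SchemaError",
    "load_task_config",
    "read_choices",
    "read_clinical",
    "read_events",
    "read_motion",
    "write_choices",
    "write_events",
]

MISSING = "."

CHOICE_COLUMNS = [
    "subject_id",
    "run",
    "trial",
    "stim_left",
    "stim_mid",
    "stim_right",
    "chosen",
    "feedback",
    "responded",
    "lag_chosen",
]

CLINICAL_RANGES = {"audit_raw": (0, 34), "cudit_raw": (0, 32), "smoking": (0, 4)}


class SchemaError(ValueError):
    """Raised when an input file violates its schema."""


def write_choices(dataset: ChoiceDataset, path: str | Path) -> None:
    """Serialize a choice dataset in the canonical TSV dialect."""
    frame = dataset.to_frame()
    out = frame.copy()
    out["feedback"] = [
        MISSING if not r else f"{f:.2f}" for r, f in zip(frame["responded"], frame["feedback"])
    ]
    out["chosen"] = [MISSING if c < 0 else str(c) for c in frame["chosen"]]
    out["lag_chosen"] = [MISSING if v < 0 else str(v) for v in frame["lag_chosen"]]
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_choices(path: str | Path, schedule: TaskSchedule | None = None) -> ChoiceDataset:
    """Parse and validate a choice TSV; reconstructs a schedule if not given.

    Without an explicit schedule, a minimal schedule is rebuilt from the
    offered-stimulus columns (payoff rates unknown, set to 0.5).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    missing = [c for c in CHOICE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    try:
        for col in ("run", "trial", "stim_left", "stim_mid", "stim_right", "responded"):
            frame[col] = frame[col].astype(int)
        frame["feedback"] = frame["feedback"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: bad dtype ({exc})") from exc
    trials = frame["trial"].to_numpy()
    if not np.array_equal(trials, np.arange(len(frame))):
        raise SchemaError(f"{path}: trials must be ordered 0..n-1")

    offered_pos = frame[["stim_left", "stim_mid", "stim_right"]].to_numpy(int)
    chosen = np.array([-1 if pd.isna(c) else int(c) for c in frame["chosen"]])
    responded = frame["responded"].to_numpy().astype(bool)
    for t in range(len(frame)):
        if responded[t] and chosen[t] not in offered_pos[t]:
            raise SchemaError(f"{path}: row {t + 2}: chosen {chosen[t]} not among offered")

    if schedule is None:
        schedule = _schedule_from_offers(offered_pos, frame["run"].to_numpy(int))
    offered = schedule.offered
    chosen_slot = np.full(len(frame), -1)
    for t in np.flatnonzero(responded):
        hits = np.flatnonzero(offered[t] == chosen[t])
        if hits.size == 0:
            raise SchemaError(f"{path}: row {t + 2}: chosen not in schedule slots")
        chosen_slot[t] = hits[0]
    feedback = frame["feedback"].to_numpy(float)
    prob_chosen = None
    if "prob_chosen" in frame.columns:
        # astype(float) parses at full precision (to_numeric does not round-trip)
        prob_chosen = frame["prob_chosen"].replace("", "nan").astype(float).to_numpy()
    return ChoiceDataset(
        subject_id=str(frame["subject_id"].iloc[0]),
        schedule=schedule,
        chosen_slot=chosen_slot,
        feedback=feedback,
        responded=responded,
        prob_chosen=prob_chosen,
    )


def _schedule_from_offers(offered_pos: np.ndarray, runs: np.ndarray) -> TaskSchedule:
    """Rebuild a minimal schedule from position-ordered offers."""
    n = offered_pos.shape[0]
    offered = np.empty_like(offered_pos)
    for t in range(n):
        row = sorted(int(s) for s in offered_pos[t])
        if len(set(row)) != 3:
            raise SchemaError(f"row {t + 2}: offered stimuli not distinct")
        if t == 0:
            offered[t] = row
            continue
        slots = list(offered[t - 1])
        new = [s for s in row if s not in slots]
        for s_new in new:
            gone = next(j for j, s in enumerate(slots) if s not in row)
            slots[gone] = s_new
        offered[t] = slots
    intro: dict[int, int] = {}
    counts: dict[int, int] = {}
    for t in range(n):
        for sid in offered[t]:
            intro.setdefault(int(sid), t)
            counts[int(sid)] = counts.get(int(sid), 0) + 1
    stimuli = {
        sid: StimulusSpec(sid, 0.5, 0.15, introduced_at=intro[sid]) for sid in sorted(intro)
    }
    n_novel = max(len(stimuli) - 3, 1)
    cfg = TaskConfig(
        n_novel_introductions=n_novel,
        lifetime_min=1,
        lifetime_max=max(counts.values()),
    )
    return TaskSchedule(
        config=cfg,
        seed=-1,
        stimuli=stimuli,
        lifetimes=counts,
        offered=offered,
        positions=np.tile(np.arange(3), (n, 1)),
        run_of_trial=runs,
    )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """BIDS-style events.tsv (onset, duration, trial_type, modulator[, run])."""
    out = events.copy()
    out["modulator"] = [
        MISSING if not np.isfinite(v) else f"{v:.6f}" for v in events["modulator"]
    ]
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_events(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
    for col in ("onset", "duration", "trial_type"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col}")
    frame["onset"] = frame["onset"].astype(float)
    frame["duration"] = frame["duration"].astype(float)
    if "modulator" in frame.columns:
        frame["modulator"] = pd.to_numeric(frame["modulator"], errors="coerce")
    if "run" not in frame.columns:
        frame["run"] = 0
    for r, grp in frame.groupby("run"):
        if (np.diff(grp["onset"].to_numpy()) < 0).any():
            raise SchemaError(f"{path}: onsets not non-decreasing within run {r}")
    return frame


def read_motion(path: str | Path) -> np.ndarray:
    """Six-column whitespace motion parameter file, one row per volume."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise SchemaError(f"{path}: expected 6 motion columns, got {arr.shape[1]}")
    return arr


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical CSV with advisory score-range checks.

    Out-of-range values are retained but warned about (range checks are
    advisory, since instruments are occasionally rescored).
    """
    frame = pd.read_csv(path)
    required = ["subject_id", "sex", "audit_raw", "cudit_raw"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col, (lo, hi) in CLINICAL_RANGES.items():
        if col in frame.columns:
            bad = frame[(frame[col] < lo) | (frame[col] > hi)]
            for idx, val in bad[col].items():
                warnings.warn(
                    f"{path}: row {idx + 2}: {col}={val} outside [{lo}, {hi}] (retained)",
                    stacklevel=2,
                )
    return frame


def load_task_config(path: str | Path) -> TaskConfig:
    """TaskConfig from a YAML mapping mirroring the dataclass fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a YAML mapping")
    task_section = raw.get("task", raw)
    valid = set(TaskConfig.__dataclass_fields__)
    unknown = set(task_section) - valid
    if unknown:
        raise SchemaError(f"{path}: unknown task config keys {sorted(unknown)}")
    try:
        return TaskConfig(**task_section)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
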