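"""Prediction-task definitions, label construction, and patient-grouped splits.

Two task families are supported:

* **static** — one prediction per stay, triggered at a fixed time after ICU
  admission (hour 12 by default), for a fixed outcome window: death within
  ``(trigger, trigger + horizon]`` hours, in-hospital death after the trigger
  (``horizon = inf``), or ICU length of stay above a threshold.
* **dynamic** — a prediction at every surviving grid time, each asking
  whether death occurs within the next 24 hours.

Stays are the sample unit but splitting is grouped by patient so that a
patient with several stays never straddles the train/validation/test
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from tbal.data_model import Cohort

SPLITS = ("train", "test", "val")


@dataclass(frozen=True)
class TaskSpec:
    """Definition of one prediction task.

    Parameters
    ----------
    kind : {"static", "dynamic"}
    trigger_h : float
        Static: the single trigger time (default hour 12).  Dynamic: the
        first trigger time; predictions are then issued at every surviving
        grid time from there on (1-hour stride on the full grid), with
        4-hourly strides used at evaluation time.
    horizon_h : float
        Label window end relative to the trigger; ``inf`` encodes the
        in-hospital (any time after trigger) outcome.  Dynamic tasks use 24.
    outcome : {"mortality", "los_gt"}
    los_threshold_h : float
        Threshold for the length-of-stay outcome (default 48 h = 2 days).
    """

    kind: str = "static"
    trigger_h: float = 12.0
    horizon_h: float = 24.0
    outcome: str = "mortality"
    los_threshold_h: float = 48.0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.outcome not in ("mortality", "los_gt"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.horizon_h > 0:
            raise ValueError("horizon_h must be positive")
        if self.kind == "dynamic" and self.outcome != "mortality":
            raise ValueError("dynamic tasks are mortality-only")

    @classmethod
    def static_mortality(cls, horizon_h: float = 24.0,
                         trigger_h: float = 12.0) -> "TaskSpec":
        return cls(kind="static", trigger_h=trigger_h, horizon_h=horizon_h,
                   outcome="mortality")

    @classmethod
    def dynamic_next24(cls, first_trigger_h: float = 1.0) -> "TaskSpec":
        return cls(kind="dynamic", trigger_h=first_trigger_h, horizon_h=24.0,
                   outcome="mortality")


def make_static_labels(cohort: Cohort, task: TaskSpec) -> pd.DataFrame:
    """One labeled example per eligible stay at the static trigger time.

    Mortality: label 1 iff ``death_time_h`` falls in
    ``(trigger, trigger + horizon]``; with an infinite horizon, 1 iff death
    occurs any time after the trigger.  Stays whose death precedes the
    trigger are excluded (their outcome is already determined).  Length of
    stay: label 1 iff ``icu_los_h > los_threshold_h``.
    """
    if task.kind != "static":
        raise ValueError("make_static_labels needs a static TaskSpec")
    rows = []
    trig = task.trigger_h
    for _, r in cohort.stays.iterrows():
        death = None if pd.isna(r.death_time_h) else float(r.death_time_h)
        if task.outcome == "mortality":
            if death is not None and death <= trig:
                continue
            if math.isinf(task.horizon_h):
                label = int(death is not None)
            else:
                label = int(death is not None
                            and trig < death <= trig + task.horizon_h)
        else:  # los_gt
            label = int(float(r.icu_los_h) > task.los_threshold_h)
        rows.append({"stay_id": str(r.stay_id), "trigger_h": trig,
                     "label": label})
    return pd.DataFrame(rows, columns=["stay_id", "trigger_h", "label"])


def make_dynamic_labels(cohort: Cohort, task: TaskSpec,
                        grid_by_stay: Mapping[str, np.ndarray]
                        ) -> pd.DataFrame:
    """Next-``horizon_h``-mortality labels at every surviving grid time.

    For each stay, every grid time ``t >= trigger_h`` (default 1 h, so the
    prefix has at least two steps of history available at hour-0 stays)
    yields one example: label 1 iff ``death_time_h in (t, t + horizon]``.
    Triggers at or after death are never emitted.  Survivors — whose absence
    of ``death_time_h`` certifies survival to hospital discharge, so the
    outcome is known at every horizon — contribute label-0 triggers through
    the end of their ICU stay.  In-hospital deaths after ICU discharge
    produce positive labels at in-ICU triggers within the horizon.
    """
    if task.kind != "dynamic":
        raise ValueError("make_dynamic_labels needs a dynamic TaskSpec")
    first = task.trigger_h if task.trigger_h > 0 else 1.0
    frames = []
    for _, r in cohort.stays.iterrows():
        sid = str(r.stay_id)
        grid = grid_by_stay.get(sid)
        if grid is None:
            continue
        death = None if pd.isna(r.death_time_h) else float(r.death_time_h)
        t = np.asarray(grid, dtype=float)
        keep = t >= first
        if death is not None:
            keep &= t < death
        t = t[keep]
        if t.size == 0:
            continue
        if death is None:
            label = np.zeros(t.size, dtype=int)
        else:
            label = ((t < death) & (death <= t + task.horizon_h)).astype(int)
        frames.append(pd.DataFrame({"stay_id": sid, "trigger_h": t,
                                    "label": label}))
    if not frames:
        return pd.DataFrame(columns=["stay_id", "trigger_h", "label"])
    return pd.concat(frames, ignore_index=True)


def split_by_patient(cohort: Cohort,
                     ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                     seed: int = 0) -> dict[str, str]:
    """Assign each patient to train/test/val with largest-remainder rounding.

    ``ratios`` are the (train, test, val) fractions (the 7:2:1 convention).
    All stays of a patient share its split.  Returns patient_id -> split.
    """
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError("ratios must sum to 1")
    patients = sorted(cohort.stays["patient_id"].astype(str).unique())
    n = len(patients)
    if n < len(SPLITS):
        raise ValueError(f"need at least {len(SPLITS)} patients, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    exact = [r * n for r in ratios]
    counts = [int(math.floor(e)) for e in exact]
    rem = n - sum(counts)
    by_frac = sorted(range(3), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in range(rem):
        counts[by_frac[i % 3]] += 1

    assignment: dict[str, str] = {}
    pos = 0
    for split, c in zip(SPLITS, counts):
        for k in order[pos:pos + c]:
            assignment[patients[k]] = split
        pos += c
    return assignment


def attach_split(labels: pd.DataFrame, cohort: Cohort,
                 assignment: Mapping[str, str]) -> pd.DataFrame:
    """Add a ``split`` column to a labels table via stay -> patient -> split."""
    stay_to_patient = dict(zip(cohort.stays["stay_id"].astype(str),
                               cohort.stays["patient_id"].astype(str)))
    out = labels.copy()
    out["split"] = [assignment[stay_to_patient[s]] for s in
                    out["stay_id"].astype(str)]
    return out


def check_no_leakage(labels: pd.DataFrame, cohort: Cohort) -> None:
    """Assert that no patient's stays appear in more than one split."""
    stay_to_patient = dict(zip(cohort.stays["stay_id"].astype(str),
                               cohort.stays["patient_id"].astype(str)))
    seen: dict[str, str] = {}
    for sid, split in zip(labels["stay_id"].astype(str), labels["split"]):
        pid = stay_to_patient[sid]
        if pid in seen and seen[pid] != split:
            raise AssertionError(
                f"patient {pid} appears in splits {seen[pid]} and {split}")
        seen[pid] = split
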