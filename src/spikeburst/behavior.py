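"""Operant-conditioning analysis: preference index and learning success.

Each training session interleaves blue (473 nm, rewarded) and red (635 nm,
unrewarded) stimulation trials. Performance per session is the preference
index (blue licks - red licks) / (blue licks + red licks); an animal has
learned once its index exceeds a threshold (default 0.2, strict) on a run of
consecutive days (default 2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .core import BehaviorSession, PreferenceTrajectory

__all__ = [
    "preference_index",
    "session_preferences",
    "learning_success",
    "LearningOutcome",
]


def preference_index(blue_licks: int, red_licks: int) -> float:
    """(blue - red) / (blue + red); NaN when both counts are zero.

    The undefined 0/0 case is deliberately NaN rather than 0: a day with no
    licking carries no preference information and is excluded from
    trajectories (and breaks consecutive-day runs) downstream.
    """
    if blue_licks < 0 or red_licks < 0:
        raise ValueError("lick counts must be non-negative")
    total = blue_licks + red_licks
    if total == 0:
        return math.nan
    return (blue_licks - red_licks) / total


def session_preferences(
    sessions: Iterable[BehaviorSession],
) -> Dict[str, PreferenceTrajectory]:
    """Per-animal, per-day preference trajectory from session lick totals.

    Sessions may belong to several animals; they are grouped by animal and
    ordered by day. Duplicate (animal, day) pairs are an error.
    """
    by_animal: Dict[str, dict] = {}
    for s in sessions:
        days = by_animal.setdefault(s.animal, {})
        if s.day in days:
            raise ValueError(f"duplicate session for animal {s.animal}, day {s.day}")
        days[s.day] = preference_index(s.blue_licks, s.red_licks)
    out = {}
    for animal, day_scores in by_animal.items():
        days = np.array(sorted(day_scores))
        scores = np.array([day_scores[d] for d in days])
        out[animal] = PreferenceTrajectory(animal, days, scores)
    return out


@dataclass
class LearningOutcome:
    """Cohort learning-success summary."""

    success: Dict[str, bool]
    first_success_day: Dict[str, Optional[int]]
    n_success: int
    n_animals: int
    rate_percent: float  # full precision
    rate_percent_rounded: int  # reported value

    @property
    def successful_animals(self) -> List[str]:
        return [a for a, ok in self.success.items() if ok]


def _first_run_day(traj: PreferenceTrajectory, threshold: float,
                   consecutive: int) -> Optional[int]:
    """Last day of the first qualifying run, or None.

    A qualifying run is >= ``consecutive`` successive days (day indices
    increasing by exactly 1) all with a defined score strictly above
    ``threshold``; undefined days break runs.
    """
    run = 0
    prev_day = None
    for day, score in zip(traj.days, traj.scores):
        ok = not np.isnan(score) and score > threshold
        contiguous = prev_day is not None and day == prev_day + 1
        run = (run + 1 if contiguous else 1) if ok else 0
        if run >= consecutive:
            return int(day)
        prev_day = day if ok else None
    return None


def learning_success(
    trajectories: Dict[str, PreferenceTrajectory],
    threshold: float = 0.2,
    consecutive: int = 2,
) -> LearningOutcome:
    """Cohort success rate under the consecutive-day preference criterion.

    An animal succeeds iff some run of >= ``consecutive`` consecutive days
    all have preference strictly above ``threshold``. The rate is reported
    rounded to the nearest percent with the full-precision value retained.
    """
    if not trajectories:
        raise ValueError("empty cohort")
    success, first_day = {}, {}
    for animal, traj in trajectories.items():
        if len(traj) < consecutive:
            success[animal], first_day[animal] = False, None
            continue
        day = _first_run_day(traj, threshold, consecutive)
        success[animal] = day is not None
        first_day[animal] = day
    n = len(success)
    k = sum(success.values())
    rate = 100.0 * k / n
    return LearningOutcome(success, first_day, k, n, rate, int(round(rate)))
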