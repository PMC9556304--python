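"""Core in-memory containers shared across the pipeline.

All times are seconds as 64-bit floats. Spike trains are per-unit ascending
arrays bounded by the recording interval; event series are labelled ascending
onset lists with per-event durations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SpikeTrainSet", "EventSeries", "BehaviorSession", "PreferenceTrajectory"]


@dataclass
class SpikeTrainSet:
    """Per-unit spike times with recording bounds.

    Parameters
    ----------
    spikes
        Mapping from unit id to spike times in seconds. Times are sorted on
        construction; exact duplicates are collapsed.
    t_start, t_stop
        Recording bounds in seconds; every spike must lie in [t_start, t_stop].
    meta
        Free-form tags (e.g. acquisition-rate label, source path).
    """

    spikes: dict
    t_start: float
    t_stop: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t_start < self.t_stop:
            raise ValueError(
                f"t_start ({self.t_start}) must be < t_stop ({self.t_stop})"
            )
        cleaned = {}
        for uid, times in self.spikes.items():
            arr = np.asarray(times, dtype=float)
            arr = np.unique(arr)  # sorts and collapses ties
            if arr.size and (arr[0] < self.t_start or arr[-1] > self.t_stop):
                raise ValueError(
                    f"unit {uid!r} has spikes outside [{self.t_start}, {self.t_stop}]"
                )
            cleaned[uid] = arr
        self.spikes = cleaned

    @property
    def unit_ids(self) -> list:
        return list(self.spikes.keys())

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def n_spikes(self) -> int:
        return int(sum(arr.size for arr in self.spikes.values()))

    def counts_in_window(self, start: float, stop: float,
                         closed: str = "left") -> np.ndarray:
        """Spike counts per unit in a window.

        ``closed='left'`` counts [start, stop); ``closed='right'`` counts
        (start, stop].
        """
        side_lo, side_hi = ("left", "left") if closed == "left" else ("right", "right")
        out = np.empty(self.n_units, dtype=int)
        for i, arr in enumerate(self.spikes.values()):
            out[i] = np.searchsorted(arr, stop, side=side_hi) - np.searchsorted(
                arr, start, side=side_lo
            )
        return out


@dataclass
class EventSeries:
    """Labelled stimulus/trial timestamps.

    ``onsets`` must be ascending; ``durations`` is broadcast to one entry per
    event. Intervals are half-open [onset, onset + duration). ``attributes``
    carries optional per-event columns (same length as ``onsets``).
    """

    label: str
    onsets: np.ndarray
    durations: np.ndarray = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) < 0):
            bad = int(np.argmax(np.diff(self.onsets) < 0)) + 1
            raise ValueError(f"onsets not ascending at row {bad}")
        if self.durations is None:
            self.durations = np.zeros_like(self.onsets)
        else:
            self.durations = np.broadcast_to(
                np.asarray(self.durations, dtype=float), self.onsets.shape
            ).copy()
        for key, col in self.attributes.items():
            arr = np.asarray(col)
            if arr.shape[0] != self.onsets.size:
                raise ValueError(f"attribute {key!r} length mismatch")
            self.attributes[key] = arr

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class BehaviorSession:
    """One animal-day of operant trials.

    ``trials`` is a DataFrame with columns ``colour`` (473 or 635), ``licks``
    (non-negative int) and ``rewarded`` (bool).
    """

    animal: str
    day: int
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"colour", "licks", "rewarded"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials missing columns: {sorted(missing)}")
        colours = set(self.trials["colour"].unique())
        if not colours <= {473, 635}:
            raise ValueError(f"unknown stimulation colours: {colours - {473, 635}}")
        if (self.trials["licks"] < 0).any():
            raise ValueError("lick counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def blue_licks(self) -> int:
        return int(self.trials.loc[self.trials["colour"] == 473, "licks"].sum())

    @property
    def red_licks(self) -> int:
        return int(self.trials.loc[self.trials["colour"] == 635, "licks"].sum())


@dataclass
class PreferenceTrajectory:
    """Per-day preference scores for one animal.

    ``scores`` holds NaN on days where the index is undefined (zero licks on
    both colours); ``defined`` marks the valid entries.
    """

    animal: str
    days: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.days.shape != self.scores.shape:
            raise ValueError("days and scores must have equal length")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def __len__(self) -> int:
        return int(self.days.size)
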