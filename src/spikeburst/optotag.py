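"""Optotagging: classify light-responsive units from pulse-aligned spiking.

A unit responds to a pulse if it fires at least one spike within the latency
window after pulse onset (window start excluded, so spikes coincident with
the light artifact do not count). Units responding on at least
``min_reliability`` of pulses (default 70%, within 10 ms) are classified as
light-responsive; both thresholds are inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EventSeries, SpikeTrainSet

__all__ = ["OptotagResult", "classify_optotagged"]


@dataclass
class OptotagResult:
    """Per-unit light-response classification.

    ``table`` columns: unit, reliability (fraction of pulses with >= 1 spike
    in the window), median_latency_s (first-spike latency over responding
    pulses; NaN when none), responsive.
    """

    table: pd.DataFrame
    max_latency: float
    min_reliability: float
    n_pulses: int

    @property
    def responsive_units(self) -> list:
        return self.table.loc[self.table["responsive"], "unit"].tolist()


def classify_optotagged(
    spikes: SpikeTrainSet,
    pulses: EventSeries,
    max_latency: float = 0.010,
    min_reliability: float = 0.7,
) -> OptotagResult:
    """Reliability/latency classification against a light-pulse train.

    Response windows are (onset, onset + max_latency]; spikes outside every
    window never affect the result.
    """
    onsets = pulses.onsets
    if onsets.size == 0:
        raise ValueError("no light pulses provided")
    if onsets.size > 1 and np.min(np.diff(onsets)) <= max_latency:
        raise ValueError(
            "pulse windows overlap: minimum onset spacing "
            f"{np.min(np.diff(onsets)):.4f} s <= max_latency {max_latency} s"
        )
    rows = []
    for unit, times in spikes.spikes.items():
        lo = np.searchsorted(times, onsets, side="right")
        hi = np.searchsorted(times, onsets + max_latency, side="right")
        responded = hi > lo
        reliability = float(responded.mean())
        if responded.any():
            first = times[lo[responded]] - onsets[responded]
            median_latency = float(np.median(first))
        else:
            median_latency = np.nan
        rows.append({
            "unit": unit,
            "reliability": reliability,
            "median_latency_s": median_latency,
            "responsive": reliability >= min_reliability,
        })
    table = pd.DataFrame(
        rows, columns=["unit", "reliability", "median_latency_s", "responsive"]
    )
    return OptotagResult(table, max_latency, min_reliability, int(onsets.size))
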