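"""Sliding-window firing rates, z-scoring, correlations and Welch spectra.

Rates are computed in overlapping half-open bins (default 200-ms windows
advanced in 100-ms steps) and optionally z-scored per unit over the whole
recording.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

from .core import SpikeTrainSet

__all__ = [
    "BinnedRates",
    "bin_firing_rates",
    "zscore_rates",
    "pairwise_correlations",
    "compare_correlation_sets",
    "welch_psd",
]

log = logging.getLogger(__name__)


@dataclass
class BinnedRates:
    """Units x bins rate matrix on a sliding-window grid.

    Bin i covers [edges[i], edges[i] + bin_width); values are Hz, or z-units
    after :func:`zscore_rates`.
    """

    matrix: np.ndarray
    unit_ids: list
    bin_width: float
    step: float
    edges: np.ndarray
    zscored: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def centers(self) -> np.ndarray:
        return self.edges + self.bin_width / 2.0


def bin_firing_rates(
    spikes: SpikeTrainSet, bin_width: float = 0.2, step: float = 0.1
) -> BinnedRates:
    """Sliding-window firing rates in Hz.

    Entry (u, i) is the count of unit u's spikes in
    [edge_i, edge_i + bin_width) divided by bin_width, with left edges at
    t_start + i*step. A trailing partial bin is dropped.
    """
    if step <= 0 or bin_width < step:
        raise ValueError(
            f"need bin_width >= step > 0 (gaps unsupported); got "
            f"bin_width={bin_width}, step={step}"
        )
    span = spikes.t_stop - spikes.t_start
    if span < bin_width:
        raise ValueError("recording shorter than one bin")
    # small epsilon so a recording length that is an exact multiple of the
    # step keeps its final full bin despite float rounding
    n_bins = int(np.floor((span - bin_width) / step + 1e-9)) + 1
    edges = spikes.t_start + step * np.arange(n_bins)
    matrix = np.empty((spikes.n_units, n_bins))
    for r, arr in enumerate(spikes.spikes.values()):
        lo = np.searchsorted(arr, edges, side="left")
        hi = np.searchsorted(arr, edges + bin_width, side="left")
        matrix[r] = (hi - lo) / bin_width
    return BinnedRates(matrix, spikes.unit_ids, bin_width, step, edges)


def zscore_rates(rates: BinnedRates) -> BinnedRates:
    """Per-unit z-score over the whole recording (sample s.d., ddof=1).

    Constant rows (e.g. silent units) map to all-zero rows with a logged
    warning rather than an error.
    """
    if rates.zscored:
        raise ValueError("rates are already z-scored")
    mean = rates.matrix.mean(axis=1, keepdims=True)
    sd = rates.matrix.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        names = [u for u, c in zip(rates.unit_ids, constant) if c]
        log.warning("constant-rate rows z-scored to zeros: %s", names)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (rates.matrix - mean) / sd_safe
    z[constant] = 0.0
    return replace(rates, matrix=z, zscored=True)


def pairwise_correlations(rates: BinnedRates):
    """Pearson correlations between unit rate rows.

    Returns ``(corr, summary)`` where ``corr`` is the units x units matrix
    (NaN for pairs involving a constant row) and ``summary`` holds the mean
    off-diagonal correlation over defined pairs and the count excluded.
    """
    if rates.n_units < 2:
        raise ValueError("need at least 2 units for pairwise correlations")
    if rates.n_bins < 3:
        raise ValueError("need at least 3 bins for pairwise correlations")
    constant = rates.matrix.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rates.matrix)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    iu = np.triu_indices(rates.n_units, k=1)
    off = corr[iu]
    defined = ~np.isnan(off)
    if not defined.any():
        raise ValueError("fewer than 2 valid (non-constant) units")
    summary = {
        "mean_offdiagonal": float(off[defined].mean()),
        "n_pairs": int(defined.sum()),
        "n_excluded_pairs": int((~defined).sum()),
    }
    return corr, summary


def offdiagonal_values(corr: np.ndarray) -> np.ndarray:
    """Defined upper-triangle correlations of a correlation matrix."""
    off = corr[np.triu_indices(corr.shape[0], k=1)]
    return off[~np.isnan(off)]


def compare_correlation_sets(corr_a: np.ndarray, corr_b: np.ndarray):
    """Rank-sum comparison of two recordings' off-diagonal correlation sets.

    Used to ask whether one population is more correlated than another (e.g.
    grafted vs. control recordings). Returns (statistic, p_value).
    """
    a, b = offdiagonal_values(corr_a), offdiagonal_values(corr_b)
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def welch_psd(x, fs: float, segment_length: int = None):
    """Welch power spectral density with Hann windows and 50% overlap.

    ``segment_length`` defaults to 10*fs samples (10-s segments). Density
    normalization: the integral over frequency approximates the signal
    variance.
    """
    x = np.asarray(x, dtype=float)
    if segment_length is None:
        segment_length = int(round(10 * fs))
    if x.size < segment_length:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one segment "
            f"({segment_length}); pass a smaller segment_length"
        )
    freqs, power = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=segment_length,
        noverlap=segment_length // 2,
        scaling="density",
    )
    return freqs, power
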