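"""Two-state discrete-emission HMM segmentation of population activity.

The population rate trace is binarized (symbol 1 = above-average population
activity), a two-state HMM is fit by Baum-Welch from fixed initial guesses
(transition [[0.95, 0.05], [0.05, 0.96]], emission [[0.5, 0.5],
[0.1, 0.99]], each row normalized to sum to 1), the state sequence is decoded
with Viterbi, and runs of the "on" state are summarized as bursts.

Everything runs in scaled space, so sequences of 1e5+ bins do not underflow.
There is no randomness anywhere in this module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import log as _log

import numpy as np
import pandas as pd

from .core import SpikeTrainSet
from .rates import BinnedRates

__all__ = [
    "ObservationSequence",
    "HMMSpec",
    "StatePath",
    "BurstStats",
    "default_initial_model",
    "binarize_population",
    "baum_welch",
    "viterbi",
    "label_bursts",
    "burst_statistics",
    "segment_bursts",
]

log = logging.getLogger(__name__)

# initial guesses for Baum-Welch; rows are normalized before use
DEFAULT_TRANSITION_GUESS = np.array([[0.95, 0.05], [0.05, 0.96]])
DEFAULT_EMISSION_GUESS = np.array([[0.5, 0.5], [0.1, 0.99]])


@dataclass
class ObservationSequence:
    """Binary population-activity symbols, one per rate bin."""

    symbols: np.ndarray
    threshold: float
    bin_width: float
    step: float
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int8)
        if self.symbols.size and not np.isin(self.symbols, (0, 1)).all():
            bad = self.symbols[~np.isin(self.symbols, (0, 1))][0]
            raise ValueError(f"symbols must be in {{0, 1}}; found {bad}")

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass
class HMMSpec:
    """Two-state model: transition, emission (state -> symbol), initial."""

    transition: np.ndarray
    emission: np.ndarray
    initial: np.ndarray
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        for name, mat in (("transition", self.transition),
                          ("emission", self.emission)):
            if np.any(mat < 0) or np.any(mat > 1):
                raise ValueError(f"{name} entries outside [0, 1]")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"{name} rows must sum to 1 within 1e-12")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


@dataclass
class StatePath:
    """Decoded per-bin state labels (1 = on/burst, 0 = off/silent)."""

    states: np.ndarray  # 0 = off, 1 = on
    on_state_index: int
    log_prob: float
    bin_width: float
    step: float
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)

    def __len__(self) -> int:
        return int(self.states.size)


@dataclass
class BurstStats:
    """Summary of interior bursts and inter-burst intervals."""

    n_bursts: int
    mean_duration_s: float
    median_duration_s: float
    mean_ibi_s: float
    mean_spikes_per_burst: float
    recruitment: float
    defined: bool = True


def default_initial_model() -> HMMSpec:
    """Row-normalized default initial guesses (uniform initial distribution).

    The raw guesses have rows summing to 1.01 (transition row 2) and 1.09
    (emission row 2); normalization is logged.
    """
    a = DEFAULT_TRANSITION_GUESS / DEFAULT_TRANSITION_GUESS.sum(axis=1, keepdims=True)
    b = DEFAULT_EMISSION_GUESS / DEFAULT_EMISSION_GUESS.sum(axis=1, keepdims=True)
    if not (np.allclose(a, DEFAULT_TRANSITION_GUESS) and
            np.allclose(b, DEFAULT_EMISSION_GUESS)):
        log.info("initial HMM guesses row-normalized before fitting")
    return HMMSpec(a, b, np.array([0.5, 0.5]))


def binarize_population(rates: BinnedRates, threshold: float = 0.0) -> ObservationSequence:
    """Binary symbol per bin: 1 iff the population-mean z exceeds threshold.

    Requires z-scored input; the comparison is strict, so an all-constant
    population (z = 0 everywhere) yields all zeros at the default threshold.
    """
    if not rates.zscored:
        raise ValueError("binarize_population requires z-scored rates")
    mean_z = rates.matrix.mean(axis=0)
    symbols = (mean_z > threshold).astype(np.int8)
    return ObservationSequence(symbols, threshold, rates.bin_width, rates.step,
                               rates.edges)


def _check_symbols(obs: ObservationSequence, emission: np.ndarray) -> None:
    for sym in np.unique(obs.symbols):
        if np.all(emission[:, sym] == 0.0):
            raise ValueError(
                f"symbol {sym} has zero emission probability in every state; "
                "smooth the initial emission matrix"
            )


def _forward_backward(obs, a, b, pi):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum).

    Pure-Python loops over time with float arithmetic: for two states this
    is substantially faster than per-step numpy dispatch and exact in scaled
    space for arbitrarily long sequences.
    """
    sym = obs.symbols
    T = sym.size
    a00, a01 = a[0]
    a10, a11 = a[1]
    # emission prob per state for each observed symbol
    e0 = (b[0, 0], b[0, 1])
    e1 = (b[1, 0], b[1, 1])

    alpha0 = [0.0] * T
    alpha1 = [0.0] * T
    scale = [0.0] * T

    s0 = int(sym[0])
    f0, f1 = pi[0] * e0[s0], pi[1] * e1[s0]
    c = f0 + f1
    if c == 0.0:
        raise ValueError("zero-probability observation at t=0")
    alpha0[0], alpha1[0], scale[0] = f0 / c, f1 / c, c
    for t in range(1, T):
        s = int(sym[t])
        p0, p1 = alpha0[t - 1], alpha1[t - 1]
        f0 = (p0 * a00 + p1 * a10) * e0[s]
        f1 = (p0 * a01 + p1 * a11) * e1[s]
        c = f0 + f1
        if c == 0.0:
            raise ValueError(f"zero-probability observation at t={t}")
        alpha0[t], alpha1[t], scale[t] = f0 / c, f1 / c, c

    loglik = float(np.sum(np.log(scale)))

    beta0, beta1 = 1.0, 1.0
    gamma0 = [0.0] * T
    gamma1 = [0.0] * T
    xi = [0.0, 0.0, 0.0, 0.0]  # summed over t: (00, 01, 10, 11)
    g0, g1 = alpha0[T - 1] * beta0, alpha1[T - 1] * beta1
    norm = g0 + g1
    gamma0[T - 1], gamma1[T - 1] = g0 / norm, g1 / norm
    for t in range(T - 2, -1, -1):
        s = int(sym[t + 1])
        c = scale[t + 1]
        eb0 = e0[s] * beta0
        eb1 = e1[s] * beta1
        nb0 = (a00 * eb0 + a01 * eb1) / c
        nb1 = (a10 * eb0 + a11 * eb1) / c
        p0, p1 = alpha0[t], alpha1[t]
        x00 = p0 * a00 * eb0 / c
        x01 = p0 * a01 * eb1 / c
        x10 = p1 * a10 * eb0 / c
        x11 = p1 * a11 * eb1 / c
        z = x00 + x01 + x10 + x11
        xi[0] += x00 / z
        xi[1] += x01 / z
        xi[2] += x10 / z
        xi[3] += x11 / z
        beta0, beta1 = nb0, nb1
        g0, g1 = p0 * beta0, p1 * beta1
        norm = g0 + g1
        gamma0[t], gamma1[t] = g0 / norm, g1 / norm

    gamma = np.column_stack([gamma0, gamma1])
    xi_sum = np.array(xi).reshape(2, 2)
    return loglik, gamma, xi_sum


def forward_loglikelihood(obs: ObservationSequence, model: HMMSpec) -> float:
    """Log P(observations | model) by the scaled forward recursion."""
    _check_symbols(obs, model.emission)
    loglik, _, _ = _forward_backward(obs, model.transition, model.emission,
                                     model.initial)
    return loglik


def baum_welch(
    obs: ObservationSequence,
    init: HMMSpec = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMSpec:
    """Baum-Welch EM re-estimation from the default (or given) initial model.

    Iterates until the relative log-likelihood improvement drops below
    ``tol`` or ``max_iter`` is reached; the returned model carries the full
    per-iteration log-likelihood trace (non-decreasing by construction).
    """
    if len(obs) < 2:
        raise ValueError("need at least 2 observations to fit")
    model = default_initial_model() if init is None else init
    _check_symbols(obs, model.emission)

    a = model.transition.copy()
    b = model.emission.copy()
    pi = model.initial.copy()
    sym = np.asarray(obs.symbols, dtype=int)
    ones_mask = sym == 1
    trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        ll, gamma, xi_sum = _forward_backward(obs, a, b, pi)
        trace.append(ll)
        if np.isfinite(prev_ll) and ll - prev_ll < tol * abs(prev_ll):
            break
        prev_ll = ll
        # M step
        denom_a = gamma[:-1].sum(axis=0)
        new_a = xi_sum / np.where(denom_a[:, None] == 0, 1.0, denom_a[:, None])
        new_a[denom_a == 0] = a[denom_a == 0]
        occ = gamma.sum(axis=0)
        em1 = gamma[ones_mask].sum(axis=0)
        new_b = np.column_stack([occ - em1, em1]) / np.where(
            occ[:, None] == 0, 1.0, occ[:, None]
        )
        new_b[occ == 0] = b[occ == 0]
        a = new_a / new_a.sum(axis=1, keepdims=True)
        b = new_b / new_b.sum(axis=1, keepdims=True)
        pi = gamma[0] / gamma[0].sum()
    return HMMSpec(a, b, pi, loglik_trace=trace)


def viterbi(obs: ObservationSequence, model: HMMSpec) -> StatePath:
    """Max-probability state path in log space.

    The "on" state is the one with larger emission probability of symbol 1
    (tie -> state index 1); path-score ties are broken toward the lower state
    index at each backtrack step.
    """
    if len(obs) == 0:
        raise ValueError("empty observation sequence")
    _check_symbols(obs, model.emission)
    sym = np.asarray(obs.symbols, dtype=int)
    T = sym.size
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transition)
        log_b = np.log(model.emission)
        log_pi = np.log(model.initial)

    n = model.n_states
    delta = log_pi + log_b[:, sym[0]]
    psi = np.zeros((T, n), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + log_a  # cand[i, j]: from i to j
        best_prev = np.argmax(cand, axis=0)  # first (lowest) index on ties
        delta = cand[best_prev, np.arange(n)] + log_b[:, sym[t]]
        psi[t] = best_prev
    last = int(np.argmax(delta))
    log_prob = float(delta[last])
    path = np.empty(T, dtype=np.int8)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]

    on_state = 1 if model.emission[1, 1] >= model.emission[0, 1] else 0
    states = (path == on_state).astype(np.int8)
    return StatePath(states, on_state, log_prob, obs.bin_width, obs.step,
                     obs.edges)


def _runs(states: np.ndarray) -> list:
    """Maximal runs as (state, start_index, length)."""
    runs = []
    start = 0
    for i in range(1, states.size + 1):
        if i == states.size or states[i] != states[start]:
            runs.append([int(states[start]), start, i - start])
            start = i
    return runs


def _merge_short_runs(runs: list, min_run: int) -> list:
    """Relabel interior runs shorter than min_run into a flanking state.

    The shortest offending run is handled first (leftmost on ties) and merged
    into its shorter neighbour (left on ties); adjacent same-state runs are
    then coalesced and the scan repeats until stable. Runs touching a
    recording boundary are never relabelled — they are truncated by the
    recording, not flicker, and are flagged non-interior downstream.
    """
    runs = [list(r) for r in runs]
    while len(runs) > 2:
        short = [(length, idx) for idx, (_, _, length) in enumerate(runs)
                 if length < min_run and 0 < idx < len(runs) - 1]
        if not short:
            break
        _, idx = min(short)
        left_len = runs[idx - 1][2]
        right_len = runs[idx + 1][2]
        target = idx - 1 if left_len <= right_len else idx + 1
        runs[idx][0] = runs[target][0]
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] += r[2]
            else:
                merged.append(r)
        runs = merged
    return runs


def label_bursts(path: StatePath, min_run: int = 2) -> pd.DataFrame:
    """On/off run table with durations and interior flags.

    Runs shorter than ``min_run`` bins are merged into a flanking state.
    Intervals span the centres of their first and last bins, so a k-bin run
    has duration (k - 1) * step — this compensates the ~one-bin outward smear
    of overlapping bins. Runs touching either recording boundary are flagged
    non-interior and excluded from duration statistics downstream.

    Returns a DataFrame with columns start_s, end_s, duration_s, state
    ('on'/'off') and interior.
    """
    runs = _merge_short_runs(_runs(path.states), min_run)
    centers = path.edges + path.bin_width / 2.0
    rows = []
    for state, start, length in runs:
        i0, i1 = start, start + length - 1
        rows.append({
            "start_s": centers[i0],
            "end_s": centers[i1],
            "duration_s": centers[i1] - centers[i0],
            "state": "on" if state == 1 else "off",
            "interior": i0 > 0 and i1 < len(path) - 1,
        })
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s",
                                       "state", "interior"])


def burst_statistics(bursts: pd.DataFrame, spikes: SpikeTrainSet) -> BurstStats:
    """Burst summary over interior runs only.

    Recruitment is the mean over interior bursts of the fraction of units
    with at least one spike inside the burst interval; spikes-per-burst
    averages spike counts over recruited (unit, burst) pairs only.
    """
    on = bursts[(bursts["state"] == "on") & bursts["interior"]]
    off = bursts[(bursts["state"] == "off") & bursts["interior"]]
    if len(on) == 0:
        return BurstStats(0, np.nan, np.nan, np.nan, np.nan, np.nan,
                          defined=False)
    fractions = []
    recruited_counts = []
    for start, end in zip(on["start_s"], on["end_s"]):
        counts = spikes.counts_in_window(start, end, closed="left")
        active = counts > 0
        fractions.append(active.mean())
        recruited_counts.extend(counts[active])
    return BurstStats(
        n_bursts=int(len(on)),
        mean_duration_s=float(on["duration_s"].mean()),
        median_duration_s=float(on["duration_s"].median()),
        mean_ibi_s=float(off["duration_s"].mean()) if len(off) else np.nan,
        mean_spikes_per_burst=(
            float(np.mean(recruited_counts)) if recruited_counts else np.nan
        ),
        recruitment=float(np.mean(fractions)),
    )


def segment_bursts(
    spikes: SpikeTrainSet,
    bin_width: float = 0.2,
    step: float = 0.1,
    threshold: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_run: int = 2,
):
    """Full burst pipeline: bin, z-score, binarize, fit, decode, summarize.

    Returns (BurstStats, burst table, fitted HMMSpec, StatePath).
    """
    from .rates import bin_firing_rates, zscore_rates

    z = zscore_rates(bin_firing_rates(spikes, bin_width, step))
    obs = binarize_population(z, threshold)
    model = baum_welch(obs, tol=tol, max_iter=max_iter)
    path = viterbi(obs, model)
    table = label_bursts(path, min_run=min_run)
    return burst_statistics(table, spikes), table, model, path
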