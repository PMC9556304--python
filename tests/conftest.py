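"""Shared fixtures and independent oracles for the test suite.

The brute-force HMM oracles enumerate every state path explicitly and are
kept independent of the package's scaled forward/Viterbi implementations.
Heavy simulations shared between module tests and acceptance checks are
session-scoped fixtures so they run once.
"""
from itertools import product

import numpy as np
import pytest

import spikeburst as sb


# --------------------------------------------------------------------------
# brute-force HMM oracles (path enumeration, tractable for T <= ~14)
# --------------------------------------------------------------------------

def enum_likelihood(symbols, transition, emission, initial) -> float:
    """P(observations) by explicit summation over all state paths."""
    n = len(initial)
    total = 0.0
    for path in product(range(n), repeat=len(symbols)):
        p = initial[path[0]] * emission[path[0], symbols[0]]
        for t in range(1, len(symbols)):
            p *= transition[path[t - 1], path[t]] * emission[path[t], symbols[t]]
        total += p
    return total


def enum_best_path(symbols, transition, emission, initial):
    """(best log-probability, best path) by explicit argmax over all paths.

    Ties are broken lexicographically toward lower state indices, matching
    the documented backtracking rule.
    """
    best_logp, best = -np.inf, None
    with np.errstate(divide="ignore"):
        la = np.log(transition)
        lb = np.log(emission)
        lpi = np.log(initial)
    for path in product(range(len(initial)), repeat=len(symbols)):
        lp = lpi[path[0]] + lb[path[0], symbols[0]]
        for t in range(1, len(symbols)):
            lp += la[path[t - 1], path[t]] + lb[path[t], symbols[t]]
        if lp > best_logp + 1e-12:
            best_logp, best = lp, path
    return best_logp, np.array(best)


def path_logprob(symbols, path, transition, emission, initial) -> float:
    """Log joint probability of one explicit state path."""
    with np.errstate(divide="ignore"):
        la = np.log(transition)
        lb = np.log(emission)
        lpi = np.log(initial)
    lp = lpi[path[0]] + lb[path[0], symbols[0]]
    for t in range(1, len(symbols)):
        lp += la[path[t - 1], path[t]] + lb[path[t], symbols[t]]
    return float(lp)


def random_model(rng) -> sb.HMMSpec:
    """Random valid two-state model with continuous entries (no ties)."""
    a = rng.dirichlet((2.0, 2.0), size=2)
    b = rng.dirichlet((2.0, 2.0), size=2)
    pi = rng.dirichlet((2.0, 2.0))
    return sb.HMMSpec(a, b, pi)


def make_obs(symbols, step=0.1, bin_width=0.2) -> sb.ObservationSequence:
    symbols = np.asarray(symbols)
    return sb.ObservationSequence(
        symbols, threshold=0.0, bin_width=bin_width, step=step,
        edges=np.arange(symbols.size) * step,
    )


# --------------------------------------------------------------------------
# reference simulation conditions
# --------------------------------------------------------------------------

def reference_population_config(seed: int) -> sb.SynthConfig:
    """600-s, 64-unit bursting population (the generator defaults)."""
    return sb.SynthConfig(seed=seed)


def reference_stimulus_config(seed: int) -> sb.SynthConfig:
    """1200-s whisker-stimulation session: 13 units, 7 kernel-modulated."""
    return sb.SynthConfig(
        duration=1200.0,
        n_units=13,
        n_events=50,
        evoked_kernel=sb.EvokedKernel(shape="alpha", amplitude_hz=6.0,
                                      peak_time_s=0.65, n_modulated=7),
        seed=seed,
    )


@pytest.fixture(scope="session")
def burst_recovery_stats():
    """Full burst pipeline on the reference population, seeds 1-3."""
    out = []
    for seed in (1, 2, 3):
        spikes, _ = sb.simulate_population(reference_population_config(seed))
        stats, _, _, _ = sb.segment_bursts(spikes)
        out.append(stats)
    return out


@pytest.fixture(scope="session")
def stimulus_recovery():
    """Modulation flags and latencies on the reference session, seeds 1-3."""
    runs = []
    for seed in (1, 2, 3):
        spikes, events, truth = sb.simulate_stimulus_session(
            reference_stimulus_config(seed)
        )
        result = sb.modulation_test(spikes, events)
        z = sb.zscore_rates(sb.bin_firing_rates(spikes))
        tensor = sb.align_trials(z, events, pre=1.0, post=2.0)
        latencies = sb.latency_to_peak(tensor)
        runs.append({"result": result, "latencies": latencies, "truth": truth,
                     "spikes": spikes, "events": events})
    return runs


def _poisson_null_units(n_units, n_events, rate_hz, seed):
    """Homogeneous Poisson units plus an event grid with no evoked response."""
    rng = np.random.default_rng(seed)
    duration = 4.0 * n_events + 8.0
    spikes = {}
    for i in range(n_units):
        n = rng.poisson(rate_hz * duration)
        spikes[f"n{i:04d}"] = np.sort(rng.uniform(0.0, duration, n))
    sts = sb.SpikeTrainSet(spikes, 0.0, duration)
    events = sb.EventSeries("whisker", 4.0 + 4.0 * np.arange(n_events),
                            durations=2.0)
    return sts, events


@pytest.fixture(scope="session")
def wilcoxon_null_fractions():
    """Flagged fractions of the modulation test on 1,000 null units.

    Computed for the real (but response-free) event grid and for a
    randomized-timestamp control series run through the same path.
    """
    sts, events = _poisson_null_units(n_units=1000, n_events=50, rate_hz=5.0,
                                      seed=2024)
    two_sided = sb.modulation_test(sts, events, direction="two_sided")
    directional = sb.modulation_test(sts, events, direction="increase")
    control = sb.random_timestamp_control(events, sts.t_start, sts.t_stop,
                                          seed=7, pre=1.0, post=1.0)
    control_res = sb.modulation_test(sts, control, direction="two_sided")
    return {
        "two_sided": two_sided.modulated_fraction,
        "directional": directional.modulated_fraction,
        "control": control_res.modulated_fraction,
    }
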