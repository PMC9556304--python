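"""HMM fitting/decoding against enumeration oracles and burst labelling."""
import numpy as np
import pytest

import spikeburst as sb
from spikeburst.hmm import _merge_short_runs, _runs
from conftest import (
    enum_best_path,
    enum_likelihood,
    make_obs,
    path_logprob,
    random_model,
)


class TestBinarize:
    def test_constant_population_yields_all_zeros(self):
        rates = sb.BinnedRates(np.zeros((3, 6)), list("abc"), 0.2, 0.1,
                               np.arange(6) * 0.1, zscored=True)
        obs = sb.binarize_population(rates)
        assert (obs.symbols == 0).all()  # strict inequality at threshold

    def test_population_mean_thresholding(self):
        mean_z = np.array([-1.0, 0.5, 2.0, -0.2])
        rates = sb.BinnedRates(np.vstack([mean_z, mean_z]), ["a", "b"],
                               0.2, 0.1, np.arange(4) * 0.1, zscored=True)
        obs = sb.binarize_population(rates)
        np.testing.assert_array_equal(obs.symbols, [0, 1, 1, 0])

    def test_sign_flip_flips_every_symbol(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 50))
        m[:, np.abs(m.mean(axis=0)) < 1e-12] += 0.1  # avoid exact-zero means
        rates = sb.BinnedRates(m, list("abcd"), 0.2, 0.1,
                               np.arange(50) * 0.1, zscored=True)
        flipped = sb.BinnedRates(-m, list("abcd"), 0.2, 0.1,
                                 np.arange(50) * 0.1, zscored=True)
        a = sb.binarize_population(rates).symbols
        b = sb.binarize_population(flipped).symbols
        np.testing.assert_array_equal(a, 1 - b)

    def test_non_zscored_input_rejected(self):
        rates = sb.BinnedRates(np.ones((2, 4)), ["a", "b"], 0.2, 0.1,
                               np.arange(4) * 0.1, zscored=False)
        with pytest.raises(ValueError, match="z-scored"):
            sb.binarize_population(rates)


class TestForwardOracle:
    def test_fixed_example_matches_enumeration(self):
        a = np.array([[0.9, 0.1], [0.2, 0.8]])
        b = np.array([[0.8, 0.2], [0.3, 0.7]])
        pi = np.array([0.5, 0.5])
        model = sb.HMMSpec(a, b, pi)
        obs = make_obs([0, 1])
        expected = enum_likelihood([0, 1], a, b, pi)
        # oracle value, frozen: sum over the 4 explicit paths
        # paths 00/01/10/11 contribute 0.072 + 0.028 + 0.006 + 0.084
        assert expected == pytest.approx(0.19, abs=1e-12)
        assert sb.forward_loglikelihood(obs, model) == pytest.approx(
            np.log(expected), abs=1e-12)

    def test_forward_equals_enumeration_over_random_models(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            model = random_model(rng)
            T = int(rng.integers(1, 13))
            sym = rng.integers(0, 2, T)
            ll = sb.forward_loglikelihood(make_obs(sym), model)
            brute = enum_likelihood(sym, model.transition, model.emission,
                                    model.initial)
            assert ll == pytest.approx(np.log(brute), abs=1e-9)


class TestViterbi:
    def test_identity_emission_recovers_symbols(self):
        model = sb.HMMSpec(np.array([[0.5, 0.5], [0.5, 0.5]]),
                           np.eye(2), np.array([0.5, 0.5]))
        sym = np.array([0, 1, 1, 0, 1])
        path = sb.viterbi(make_obs(sym), model)
        np.testing.assert_array_equal(path.states, sym)

    def test_path_attains_bruteforce_maximum_over_random_models(self):
        """The decoded path's explicit joint log-probability equals the
        enumeration maximum (paths may differ only on exact score ties)."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            model = random_model(rng)
            T = int(rng.integers(1, 13))
            sym = rng.integers(0, 2, T)
            path = sb.viterbi(make_obs(sym), model)
            best_logp, _ = enum_best_path(sym, model.transition,
                                          model.emission, model.initial)
            assert path.log_prob == pytest.approx(best_logp, abs=1e-9)
            on = path.on_state_index
            decoded = np.where(path.states == 1, on, 1 - on)
            scored = path_logprob(sym, decoded, model.transition,
                                  model.emission, model.initial)
            assert scored == pytest.approx(best_logp, abs=1e-9)

    def test_fully_symmetric_model_returns_all_off(self):
        model = sb.HMMSpec(np.full((2, 2), 0.5), np.full((2, 2), 0.5),
                           np.array([0.5, 0.5]))
        path = sb.viterbi(make_obs([1, 1, 0, 1]), model)
        # every path ties; tie rules force state 0, which maps to "off"
        assert path.on_state_index == 1
        assert (path.states == 0).all()


class TestBaumWelch:
    def test_default_initial_guesses_row_normalized(self):
        model = sb.default_initial_model()
        np.testing.assert_allclose(model.transition[0], [0.95, 0.05])
        np.testing.assert_allclose(model.transition[1],
                                   [0.05 / 1.01, 0.96 / 1.01])
        np.testing.assert_allclose(model.emission[0], [0.5, 0.5])
        np.testing.assert_allclose(model.emission[1],
                                   [0.1 / 1.09, 0.99 / 1.09])
        np.testing.assert_allclose(model.initial, [0.5, 0.5])

    def test_loglik_trace_monotone_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            sym = rng.integers(0, 2, int(rng.integers(20, 200)))
            fitted = sb.baum_welch(make_obs(sym), init=random_model(rng),
                                   max_iter=60)
            trace = np.array(fitted.loglik_trace)
            assert (np.diff(trace) >= -1e-9).all()

    def test_reestimated_rows_remain_stochastic(self):
        rng = np.random.default_rng(4)
        sym = rng.integers(0, 2, 300)
        fitted = sb.baum_welch(make_obs(sym))
        np.testing.assert_allclose(fitted.transition.sum(axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(fitted.emission.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_degenerate_all_ones_sequence(self):
        obs = make_obs(np.ones(50, dtype=int))
        fitted = sb.baum_welch(obs)
        trace = np.array(fitted.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()
        # the fitted model must explain a constant-1 sequence almost surely
        assert sb.forward_loglikelihood(obs, fitted) > -1e-3

    def test_zero_probability_lock_detected(self):
        model = sb.HMMSpec(np.array([[0.9, 0.1], [0.1, 0.9]]),
                           np.array([[1.0, 0.0], [1.0, 0.0]]),
                           np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="smooth"):
            sb.baum_welch(make_obs([0, 1, 0]), init=model)

    def test_bad_symbols_rejected(self):
        with pytest.raises(ValueError, match="symbols"):
            make_obs([0, 2, 1])

    def test_agrees_with_hmmlearn_forward_scoring(self):
        """Independent cross-check: scaled forward log-likelihood matches
        hmmlearn's CategoricalHMM.score for fixed parameters."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(12)
        sym = rng.integers(0, 2, 500)
        model = sb.default_initial_model()
        ref = hmmlearn.CategoricalHMM(n_components=2, init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.emissionprob_ = model.emission
        expected = ref.score(sym.reshape(-1, 1))
        assert sb.forward_loglikelihood(make_obs(sym), model) == pytest.approx(
            expected, abs=1e-8)

    def test_recovers_geometric_self_transitions(self):
        """On geometric-dwell simulations the fitted self-transition
        probabilities match the bin-resolution-corrected generative values."""
        step = 0.1
        errs = []
        for seed in (1, 2, 3):
            cfg = sb.SynthConfig(
                duration=600.0, n_units=64,
                on_dwell=sb.DistSpec("geometric", (0.5,)),
                off_dwell=sb.DistSpec("geometric", (2.0,)),
                seed=seed,
            )
            spikes, _ = sb.simulate_population(cfg)
            z = sb.zscore_rates(sb.bin_firing_rates(spikes, bin_width=step,
                                                    step=step))
            obs = sb.binarize_population(z)
            fitted = sb.baum_welch(obs)
            on = 1 if fitted.emission[1, 1] >= fitted.emission[0, 1] else 0
            # geometric(10-ms tick, mean m): P(survive a 100-ms bin) = (1-p)^10
            expect_on = (1 - 0.01 / 0.5) ** 10
            expect_off = (1 - 0.01 / 2.0) ** 10
            errs.append(abs(fitted.transition[on, on] - expect_on))
            errs.append(abs(fitted.transition[1 - on, 1 - on] - expect_off))
        assert max(errs) < 0.05


class TestBurstLabelling:
    def test_all_off_path_yields_no_bursts(self):
        path = sb.StatePath(np.zeros(10, dtype=int), 1, 0.0, 0.2, 0.1,
                            np.arange(10) * 0.1)
        table = sb.label_bursts(path)
        assert (table["state"] == "off").all()

    def test_interior_run_duration_convention(self):
        path = sb.StatePath(np.array([0, 1, 1, 1, 0]), 1, 0.0, 0.2, 0.1,
                            np.arange(5) * 0.1)
        table = sb.label_bursts(path)
        on = table[table["state"] == "on"]
        assert len(on) == 1
        assert on.iloc[0]["duration_s"] == pytest.approx(0.2)  # (3-1)*0.1
        assert bool(on.iloc[0]["interior"])

    def test_boundary_runs_flagged_non_interior(self):
        path = sb.StatePath(np.array([1, 1, 0, 0, 1, 1, 0, 0]), 1, 0.0,
                            0.2, 0.1, np.arange(8) * 0.1)
        table = sb.label_bursts(path)
        assert not table.iloc[0]["interior"]  # leading burst
        assert not table.iloc[-1]["interior"]  # trailing off-run
        stats = sb.burst_statistics(
            table, sb.SpikeTrainSet({"u": [0.45]}, 0.0, 1.0))
        assert stats.n_bursts == 1  # only the interior burst counts

    def test_short_runs_merged_into_flank(self):
        states = np.array([0, 0, 0, 1, 0, 0, 1, 1, 1, 0, 0])
        merged = _merge_short_runs(_runs(states), min_run=2)
        # the singleton on-run dissolves into the surrounding off state
        labels = [state for state, _, _ in merged]
        lengths = [length for _, _, length in merged]
        assert labels == [0, 1, 0]
        assert lengths == [6, 3, 2]

    def test_intervals_ascending_and_disjoint(self):
        rng = np.random.default_rng(8)
        states = (rng.random(200) < 0.3).astype(int)
        path = sb.StatePath(states, 1, 0.0, 0.2, 0.1, np.arange(200) * 0.1)
        table = sb.label_bursts(path)
        assert (table["start_s"].diff().dropna() > 0).all()
        assert (table["end_s"].to_numpy()[:-1] <= table["start_s"].to_numpy()[1:]).all()


class TestBurstStatistics:
    def test_hand_counted_recruitment_and_spikes(self):
        import pandas as pd
        table = pd.DataFrame({
            "start_s": [1.0], "end_s": [1.5], "duration_s": [0.5],
            "state": ["on"], "interior": [True],
        })
        spikes = sb.SpikeTrainSet({"A": [1.1, 1.2], "B": []}, 0.0, 3.0)
        stats = sb.burst_statistics(table, spikes)
        assert stats.recruitment == pytest.approx(0.5)
        assert stats.mean_spikes_per_burst == pytest.approx(2.0)

    def test_full_participation_gives_unit_recruitment(self):
        import pandas as pd
        spikes, truth = sb.simulate_population(sb.SynthConfig(
            duration=120.0, n_units=8, recruit_prob=1.0, noise_rate=0.0, seed=1))
        bursts = truth.burst_intervals
        table = pd.DataFrame({
            "start_s": [s for s, _ in bursts],
            "end_s": [e for _, e in bursts],
            "duration_s": [e - s for s, e in bursts],
            "state": "on",
            "interior": True,
        })
        stats = sb.burst_statistics(table, spikes)
        assert stats.recruitment == pytest.approx(1.0)

    def test_no_interior_bursts_flagged_undefined(self):
        path = sb.StatePath(np.array([1, 1, 1, 1]), 1, 0.0, 0.2, 0.1,
                            np.arange(4) * 0.1)
        stats = sb.burst_statistics(sb.label_bursts(path),
                                    sb.SpikeTrainSet({"u": [0.1]}, 0.0, 1.0))
        assert not stats.defined and stats.n_bursts == 0
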