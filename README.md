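# spikeburst

Analysis pipeline for in vivo population spike-train recordings that exhibit
synchronous bursting — such as extracellular recordings from human cortical
organoid grafts in rodent cortex — together with the stimulus-response,
optotagging and operant-behaviour analyses that accompany such recordings,
and a synthetic-data generator that provides ground truth for every stage.

## What it computes

**Burst segmentation.** Firing rates are computed per unit in 200-ms bins
sliding by 100 ms and converted to z-scores. The population-mean z trace is
binarized (symbol 1 ⇔ above-average activity) and modelled with a two-state
hidden Markov model with discrete emissions,

- transition matrix A (2×2, row-stochastic), emission matrix B (state →
  symbol probabilities), fit by Baum–Welch (EM over the scaled
  forward–backward recursions) from fixed initial guesses
  A₀ = [[0.95, 0.05], [0.05, 0.96]], B₀ = [[0.5, 0.5], [0.1, 0.99]]
  (rows normalized), convergence when the relative log-likelihood
  improvement falls below 10⁻⁶;
- the state path is decoded with the Viterbi algorithm; runs of the "on"
  state are bursts, runs of "off" are inter-burst intervals.

Burst statistics: mean/median burst duration, mean inter-burst interval,
recruitment (fraction of units firing ≥ 1 spike inside a burst), and spikes
per recruited (unit, burst) pair.

**Sensory modulation.** Per unit, per-trial spike counts 1 s after vs. 1 s
before each whisker-deflection onset are compared with a paired Wilcoxon
signed-rank test (α = 0.05); a unit is modulated when p < α with a positive
median shift. Response latency is the time to the peak of the trial-averaged
z-scored rate within 2 s of onset. A randomized-timestamp control reruns the
identical path on shuffled event times.

**Optotagging.** A unit is light-responsive when it spikes within 10 ms of
pulse onset on ≥ 70% of pulses (protocol: ten 10-ms, 473-nm pulses at 2 Hz).

**Operant learning.** Per training session, the preference index
(blue-trial licks − red-trial licks)/(blue + red); an animal has learned
once its index is > 0.2 on ≥ 2 consecutive days, and the cohort learning
success rate is the percentage of animals that do.

Also included: pairwise Pearson rate correlations with a rank-sum group
comparison, Welch power spectral density (10-s Hann segments, 50% overlap),
and readers/writers for spike/event TSV tables, phy-style sorter
directories, behaviour CSV logs, JSON results and YAML configs.

## Worked example

`examples/burst_detection.py` simulates the reference conditions — 600 s,
64 units, a latent on/off process with gamma dwell times (mean on 0.46 s,
mean off 2.0 s), 73% per-burst recruitment, 1 + Poisson(2) spikes per
recruited unit per burst, 0.05 Hz background noise — and runs the full
pipeline:

```
simulated 64 units, 37797 spikes, 256 true bursts
detected interior bursts : 254
mean burst duration      : 490 ms (generative 460 ms)
mean inter-burst interval: 1.67 s (generative 2.0 s)
spikes per recruited pair: 2.95 (generative 3)
recruitment fraction     : 73.3% (generative 73%)
Baum-Welch iterations    : 14; final log-likelihood -1667.2
```

The detector recovers the generative burst structure from spikes alone:
duration, spikes-per-burst and recruitment within a few percent, and the
inter-burst interval within the documented ~10% shortening introduced by the
bin-smear-compensating duration convention (see `docs/methods.md`). The
other scripts in `examples/` cover sensory modulation and latency,
optotagging classification, and the behavioural learning criterion.

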