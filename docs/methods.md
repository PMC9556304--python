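# Methods

This note documents the models and procedures implemented in `spikeburst`,
the choices made where a convention had to be fixed, and what the synthetic
generator does and does not emulate.

## Rate estimation and binarization

Firing rates are computed per unit in half-open sliding windows
[t₀ + i·step, t₀ + i·step + width), defaults width = 0.2 s and step = 0.1 s;
the trailing partial bin is dropped. Z-scoring is per unit over the whole
recording with the sample (n−1) standard deviation; constant rows (silent
units) map to all-zero rows with a logged warning rather than an error,
since real recordings contain silent units. A per-trial-window z-score
variant is intentionally not the default — whole-recording normalization
keeps burst and stimulus analyses on one scale.

The two-state HMM takes a binary observable. How that observable is built
from the z-scored rates is a genuine design choice (a 2×2 emission matrix
only constrains it to be binary); we binarize the **population-mean**
z-score at a threshold of 0, so symbol 1 means above-average population
activity. Per-channel binarization is a plausible alternative; the threshold
is configurable.

## Two-state HMM

Baum–Welch runs on the scaled forward–backward recursions (per-step
normalization, log-likelihood accumulated from the scale factors), so
sequences of 10⁵+ bins do not underflow. The recursions are written as
plain-float loops specialized to two states, which is faster than per-step
array dispatch at these sizes. Initial guesses are the fixed matrices
A₀ = [[0.95, 0.05], [0.05, 0.96]] and B₀ = [[0.5, 0.5], [0.1, 0.99]]. Note
neither A₀'s second row (sum 1.01) nor B₀'s second row (sum 1.09) is
stochastic as printed; both are row-normalized before use and the adjustment
is logged. The initial state distribution is uniform. Convergence is
declared when the relative improvement in log-likelihood drops below 10⁻⁶
(metric chosen here; the threshold value is the conventional one), with a
500-iteration cap. The EM trace is retained and is non-decreasing within
1e-9 — a property the test suite asserts on random inputs, alongside exact
agreement of the forward likelihood and Viterbi score with brute-force path
enumeration for short sequences.

Viterbi decoding runs in log space. The "on" state is the one with larger
emission probability of symbol 1 (tie → state index 1); path-score ties
break toward the lower state index at each backtrack step, which makes
decoding fully deterministic (a fully symmetric model decodes to all-off).

## Burst labelling conventions

A 200-ms window sliding by 100 ms smears each true burst outward by roughly
one bin at each edge. Two conventions compensate:

- a k-bin run spans the **centres** of its first and last bins, so its
  duration is (k − 1) × step;
- runs shorter than `min_run` = 2 bins are considered flicker and merged
  into a flanking state (into the shorter neighbour, left on ties), unless
  they touch a recording boundary — boundary runs are truncated by the
  recording, not flicker, so they are kept but flagged non-interior and
  excluded from all duration/recruitment statistics.

With the reference geometry these conventions recover burst durations
essentially unbiased (≈ 0.47–0.49 s for a generative 0.46 s). They are not
free for the off-state: each burst's outward smear is paid for by its
flanking silent periods, so recovered inter-burst intervals run ≈ 10% short
(≈ 1.75–1.8 s for a generative 2.0 s). We keep one convention for both run
types rather than tuning them independently; the bias is systematic, small
relative to the dwell itself, and documented here.

"Spikes per burst" averages over **recruited** (unit, burst) pairs only —
averaging over all units would make the statistic redundant with
recruitment; the all-units variant is a one-line change on the returned
counts.

## Modulation testing

The paired Wilcoxon signed-rank test compares per-trial spike counts in
(onset, onset + 1 s] against [onset − 1 s, onset). Zero differences are
dropped (Wilcoxon's convention); the exact null distribution is used for
≤ 25 non-zero, untied differences and the normal approximation with
continuity correction otherwise (spike counts tie heavily, so the exact
branch mostly serves small clean inputs). The default `modulated` flag is
one-directional — p < α **and** a positive median shift — matching an
analysis that reports significant *increases*; the flag's null rate is
therefore below α (≈ α/2). The two-sided flag (`direction="two_sided"`) is
what the type-I-error calibration checks: on 1,000 simulated null units its
flagged fraction is 0.05 ± 0.02, and the randomized-timestamp control run
through the identical path behaves the same. No multiple-comparison
correction is applied by default, mirroring the single-unit reporting
convention the pipeline reproduces.

Trial alignment snaps each event to the nearest bin centre and takes an
inclusive lag grid at the rate step (pre = 1 s, post = 2 s → 31 lags; 21
when post = 1 s). Lags are labelled by bin **centre**, which keeps the
latency-to-peak estimator unbiased to within one step for noiseless kernel
responses (left-edge labelling would bias it half a window early). Latency
is the argmax of the trial-averaged trace over (0, 2 s]; traces whose
maximum sits at the first positive lag (flat or monotone-decreasing) are
flagged degenerate.

## Optotagging

Response windows are (onset, onset + 10 ms]: the left edge is open so a
spike exactly at pulse onset — typically a light artifact — never counts.
Both thresholds are inclusive ("within 10 ms", "70% or more"), and *any*
spike in the window counts as a response (the criterion does not require the
first spike to be in-window). Reported latency is the median first-spike
latency over responding pulses.

## Behaviour

The preference index is exactly (blue − red)/(blue + red) on session lick
totals. A 0/0 session is **undefined** (NaN), not zero: it is excluded from
trajectories and breaks consecutive-day runs — the conservative reading of
a criterion that demands evidence of preference on consecutive days. The
threshold comparison is strict (> 0.2), and runs require day indices
consecutive by exactly 1 (a missing day breaks a run). The cohort rate is
reported rounded to the nearest percent with the exact fraction retained.

## Synthetic generator

The generator emulates exactly the structure the analyses assume:

- a latent alternating on/off process with independent dwell draws — gamma
  with shape 4 by default (on: scale 0.115 s → mean 0.46 s; off: scale
  0.5 s → mean 2.0 s). Gamma rather than geometric/exponential suppresses
  sub-bin dwells the 200-ms analysis cannot resolve; a geometric family (on
  a 10-ms tick) exists for Markov-consistency checks, and a `fixed` family
  for degenerate tests. Dwell means below twice the 10-ms tick trigger a
  warning;
- per burst, each unit is recruited independently with probability 0.73 and
  places 1 + Poisson(2) spikes uniformly within the burst;
- homogeneous Poisson background noise (0.05 Hz per unit) over the whole
  recording — not off-state-only, which stresses the detector more
  realistically;
- evoked responses are *added* as an inhomogeneous Poisson process from an
  alpha (or boxcar) kernel after each event (superposition, not thinning),
  for a randomly chosen subset of units; events are placed uniformly with a
  minimum separation of 4 s and 2-s edge margins via the order-statistics
  construction (sorted uniforms on the separation-reduced range), which is
  distributionally identical to rejection sampling but O(1) in attempts;
- optotagged units answer each pulse with probability `reliability` by one
  spike at latency |Normal(4 ms, jitter)| truncated to (0, 10 ms];
- behaviour cohorts: learners' expected blue licks ramp 10 + 6·(day − 1)
  with red flat at 40 (per-trial Poisson); the deterministic `fixture_F1`
  spreads those totals exactly over 150 + 150 trials, giving eight animals
  that cross the 0.2 threshold from day 10 and one that never does (8/9 →
  89%).

All randomness flows from a single `numpy` generator seeded per call; the
same config and seed give bit-identical output.

**What passing tests do not show.** The generator has no refractory
periods, no unit-specific rates or waveforms, no drift or sorting errors,
no LFP, and its bursts recruit units independently rather than through any
circuit structure. Recovery of the generative statistics therefore
validates the *estimators* under the model's assumptions; it is not
evidence about any particular biological recording.

## Problem sizes

Recovery checks use 600-s, 64-unit populations (three seeds) for burst
statistics and 1,200-s, 13-unit sessions with 50 events (three seeds) for
modulation and latency; calibration checks use 1,000 simulated null or
tagged units. These sizes put Monte-Carlo error well inside the stated
tolerances while keeping the full suite inside a couple of minutes.
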