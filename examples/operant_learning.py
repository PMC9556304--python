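"""Score operant learning from multi-day lick logs.

Each session interleaves 150 blue (473-nm, rewarded) and 150 red (635-nm,
unrewarded) stimulation trials; performance is the preference index
(blue - red)/(blue + red) on session lick totals, and an animal has learned
once its index exceeds 0.2 on two consecutive days. The deterministic
9-animal fixture has eight learners and one indifferent animal.
"""
import spikeburst as sb

sessions = [s for animal in sb.fixture_F1() for s in animal]
trajectories = sb.session_preferences(sessions)
outcome = sb.learning_success(trajectories, threshold=0.2, consecutive=2)

a1 = trajectories["A1"]
print("animal A1 preference by day:",
      " ".join(f"{s:+.2f}" for s in a1.scores))
print(f"learning success: {outcome.n_success}/{outcome.n_animals} animals "
      f"-> {outcome.rate_percent_rounded}% "
      f"(exact {outcome.rate_percent:.1f}%)")
print("first success day per learner:",
      {a: d for a, d in outcome.first_success_day.items() if d is not None})

# A stochastic non-learner cohort stays near zero preference throughout.
cohort = sb.simulate_behavior_cohort(9, 15, [False] * 9, seed=2)
flat = sb.session_preferences([s for a in cohort for s in a])
null_rate = sb.learning_success(flat).rate_percent_rounded
print(f"control cohort (no learners) success rate: {null_rate}%")
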