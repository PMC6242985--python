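"""Classify trials by locomotion state and summarize the behavior.

A trial is locomotion if speed > 1 cm/s for at least 80% of its duration,
stationary if speed < 0.25 cm/s for at least 80%, and unclassified
otherwise. Bout statistics report the alternation structure of the session.
"""

import spikestate as ss

config = ss.SynthConfig(rng_seed=2, session_length=720.0,
                        unit_specs=(ss.UnitSpec("u0"),))
trace, bouts = ss.generate_behavior(config)
trials = ss.generate_trials(config, "tf")

labeled = ss.classify_trials(trace, trials)
print("trial states:", labeled["state"].value_counts().to_dict())

summary = ss.bout_statistics(trace)
print(f"locomotion bouts: median {summary.median_duration['locomotion']:.1f} s, "
      f"mean {summary.mean_duration['locomotion']:.1f} s")
print(f"stationary bouts: median {summary.median_duration['stationary']:.1f} s, "
      f"mean {summary.mean_duration['stationary']:.1f} s")

# pupil dilates quickly at locomotion onset and constricts slowly afterward
events = {
    "locomotion": bouts.loc[bouts["state"] == "locomotion", "start"].to_numpy()[1:],
    "stationary": bouts.loc[bouts["state"] == "stationary", "start"].to_numpy()[1:],
}
pupil = ss.state_triggered_average(trace, events, window=(0.0, 4.0))
for state in ("locomotion", "stationary"):
    m = pupil[state]["mean"]
    print(f"pupil after {state} onset: {m[0]:.2f} -> {m[-1]:.2f} mm")
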