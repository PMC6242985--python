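# spikestate

State-dependent analysis of visual spike-train responses.

`spikestate` quantifies how a behavioral state — locomotion versus
stationary rest on a treadmill — modulates the visual responses of
extracellularly recorded neurons, in the style of awake-mouse dLGN/V1
experiments with drifting-grating and contrast-reversal stimulation. It is
aimed at systems neuroscientists who have per-unit spike times, a stimulus
trial table and a running-speed trace, and want the full analysis battery:
trial classification by state, response statistics with a permutation null,
modulation indices, variability and correlation measures, tuning fits and
functional cell typing. A fully seeded synthetic-session generator with
ground truth makes every stage verifiable without recordings.

## The statistics at the core

* **F0 / F1.** Over an integer number of stimulus cycles, F0 is the mean
  rate and the complex first harmonic is
  `F1 = (2/T) Σ_k exp(−i 2π f t_k)`, so a rate `b + A·cos(2π f t)` yields
  amplitude `A`. Two across-trial reductions are kept: the mean per-trial
  modulus (used for trial-to-trial variability; carries a finite-count
  noise floor) and the phase-coherent `|mean F1|` (the amplitude estimator).
* **Responsiveness (VEI).** Each trial's inter-spike intervals are shuffled,
  preserving count, first-spike latency and the ISI multiset while
  destroying stimulus locking. The visual-evoked index is the mean over
  conditions of the distance between observed and shuffled coherent F1
  amplitudes; units with VEI > 2 spikes/s count as responsive, and
  `normalized F1 = F1 / F1_permuted` references locking to the shuffle
  floor.
* **Modulation index.** An origin-constrained least-squares line through
  (stationary mean, locomotion mean) pairs across conditions:
  `slope = Σ stat·loco / Σ stat²`, `MI = slope − 1`; MI = 0.36 reads as a
  36% increase while running.
* **Variability.** Fano factor of 50-ms spike counts across ≥ 10 repeated
  trials (Poisson ⇒ 1; shared-gain noise ⇒ `1 + CV²·mean count`), plus the
  across-trial variance and CV of per-trial F1.
* **Correlations.** Stimulus-corrected cross-correlograms at 1-ms lags and
  the windowed statistic
  `r_CCG(t) = Σ_{|τ|≤t} CCG(τ) / sqrt(Σ ACG₁ · Σ ACG₂)`, which converges to
  the spike-count correlation `r_SC` (Pearson over per-trial counts in a
  1-s window starting 0.5 s after onset, delete-one jackknife SE) as the
  window grows; an exponential fit gives the correlation timescale.
* **Tuning.** A two-sided Gaussian on the octave axis:
  `R(ω) = b₁ + (a − b₁)·exp(−((x_p − x)/s)²)` below the preferred frequency
  and the analogous branch with `b₂` above (`x = log2 ω`); fits with
  variance explained ≤ 0.9 are excluded, and bandwidth is the FWHM above
  the larger baseline, in octaves.
* **Cell typing.** k-means (k = 3) over concatenated, peak-normalized
  cycle averages across the spatial-frequency conditions + blank separates
  nonlinear high-SF, mid-SF-tuned and high-baseline response families;
  1 Hz contrast-reversal cycle averages yield a 4-way transient/sustained
  ON/OFF classification (units driven in both half-cycles are excluded),
  and group-wise MI distributions are compared with two-sample K–S tests.

## A worked example

```python
import numpy as np
import spikestate as ss

spec = ss.UnitSpec("u", baseline_rate=8.0, tuning=(4.0, 8.0, 1.5, 3.0, 3.0),
                   loco_gain=1.35, gain_noise_cv=0.2)
config = ss.SynthConfig(rng_seed=4, session_length=1080.0, unit_specs=(spec,))
session = ss.simulate_session(config, "tf")
trials = ss.classify_trials(session.trace, session.trials)

per_state = {state: {s.condition: s for s in ss.condition_summary(
                 session.trains[0], trials, state=state, min_trials=8)}
             for state in ("stationary", "locomotion")}
conds = sorted(set(per_state["stationary"]) & set(per_state["locomotion"]) - {"blank"})
stat = np.array([per_state["stationary"][c].f0 for c in conds])
loco = np.array([per_state["locomotion"][c].f0 for c in conds])
r = ss.modulation_index(stat, loco, measure="F0")
print(f"F0 modulation: slope {r.slope:.2f}, MI {r.mi:+.2f}")
```

prints (seed 4)

```
F0 modulation: slope 1.37, MI +0.37
```

i.e. the unit fires 37% more during locomotion across conditions — the
origin-constrained fit recovers the generator's true behavioral gain of
1.35 up to trial noise. `examples/` contains one short script per
capability (simulation, behavior, responses, modulation/variability,
correlations, tuning, cell typing), each printing the numbers it computes
and what they mean.

A thin CLI mirrors the pipeline for shell use:

```bash
spikestate simulate --experiment tf --seed 1 --out session/
spikestate run-all --experiment tf --spikes session/spikes.tsv \
    --trials session/trials.tsv --behavior session/behavior.tsv \
    --seed 1 --out results/
```

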