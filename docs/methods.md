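# Methods

This note documents the models, estimators and design choices behind
`spikestate`, and what the synthetic-data generator does and does not
emulate.

## The synthetic session model

The generator produces the three objects the analyses consume — a behavior
trace, a trial table and spike trains — from one integer seed (three
deterministic child streams, so regenerating the behavior never reshuffles
the spikes).

**Behavior.** Locomotion and stationary bouts alternate with log-normal
durations parameterized by their medians (defaults 6.4 s and 8.8 s) and a
shape parameter sigma = 0.8; the log-normal was chosen for its heavy right
tail, which matches how treadmill bouts distribute, and sigma is exposed
because only the medians are well constrained. Locomotion speed is drawn
per 60-Hz sample from a gamma distribution matched to a mean of 13.6 cm/s
and SD of 11.9 cm/s (a gamma is the natural positive-support choice when
only two moments are known), lightly smoothed (3-sample moving average)
within each bout; stationary speed is uniform below 0.25 cm/s. The optional
pupil channel relaxes exponentially toward a state-dependent diameter
(1.6 mm stationary, 2.3 mm running) with asymmetric time constants (0.7 s
dilation, 2.5 s constriction), reproducing fast dilation at movement onset
and slow constriction at rest.

**Stimuli.** Trials are 2 s, separated by a 1-s gray gap, scheduled in
shuffled blocks covering every condition plus a blank: five temporal
frequencies (1–16 Hz), five spatial frequencies (0.01–0.16 cpd), or
full-field contrast reversal at 1 Hz (three reversal trials per blank so
reversal cycle counts stay high). The default 720-s session yields 40
repeats per condition, inside the 30–50 range the analyses assume. The
drift rate of spatial-frequency gratings is not separately constrained and
defaults to 2 Hz (`sf_drift_tf`).

**Spikes.** Each unit is an inhomogeneous Poisson process thinned against a
single per-unit envelope; if the realized rate ever exceeds the envelope an
error is raised rather than clipping. The rate is
`g(t) · max(0, b + stimulus terms)` with `g(t)` the product of the
behavioral gain (`loco_gain` whenever the animal is inside a locomotion
bout), a per-trial log-normal private gain with configurable CV, and a
per-trial shared log-normal factor common to all units with
`shared_noise_weight > 0` (all gain factors have mean 1 by construction, so
they add variability without changing mean rates). Stimulus terms by cell
class:

* *linear-tuned* (and the ON/OFF classes during gratings):
  `A(cond)·cos(2π f t − φ)` with `A` from the two-Gaussian tuning curve;
* *nonlinear-highSF*: additionally a rate elevation and a
  frequency-doubled component (both of size `f2_weight`) at the two highest
  spatial frequencies — the signature of nonlinear spatial summation;
* *transient/sustained ON/OFF*: half-wave exponential-decay templates
  locked to the 1-Hz reversal, decay 50 ms (transient) vs 400 ms
  (sustained), chosen so the transient peak clearly precedes the sustained
  plateau within a half-cycle; both constants are per-unit fields;
* *suppressed*: a negative rate offset during stimulation.

Spiking is Poisson without refractoriness by default; note that rectifying
`max(0, ·)` compresses the realized F1 below the nominal amplitude whenever
`A > b`, so ground-truth amplitude checks use configurations with `A ≤ b`.

**What the generator does not emulate.** No membrane or network dynamics,
no spike-sorting artifacts, no refractory structure (the ISI-permutation
null is exactly rate-preserving only for renewal-like trains), no
sub-trial timescale in the shared gain (count correlations therefore
accumulate over the whole trial), no eye movements, and no slow
non-stationarities (drift, adaptation). Passing the recovery tests
demonstrates that the estimators are correct under these assumptions, not
that real recordings satisfy them.

## Estimators and conventions

**Analysis windows** are truncated to a whole number of stimulus cycles
from trial onset (at 1 Hz a 2-s trial is exactly two cycles; the truncation
matters only for irregular inputs). Intervals are half-open
`[onset, onset + duration)` throughout; times are seconds on a 0-based
session clock.

**F0/F1.** The complex F1 is `(2/T) Σ exp(−i 2π f (t_k − onset))`. Two
across-trial reductions coexist deliberately. The mean per-trial modulus
keeps a scalar per trial — required for trial-to-trial F1 variance and CV —
but carries a positive finite-count floor (a homogeneous Poisson train of
rate λ has `E|F1| ≈ sqrt(π λ / T)`), which is exactly what the
ISI-permutation null estimates and the normalized F1 divides out. The
phase-coherent `|mean F1|` averages that floor away and is the estimator
used when the amplitude itself is the quantity of interest (tuning fits,
amplitude-recovery checks). Reports that quote peak-to-peak amplitudes are
twice the stored peak amplitude.

**Trial classification** integrates the threshold indicator time-weighted
over the trial with piecewise-constant interpolation, so irregular sampling
cannot bias occupancy; both criteria use ≥ 80% (the boundary at exactly 80%
is not otherwise constrained). Bout segmentation merges bouts shorter than
0.5 s into their neighbor — jitter at threshold crossings otherwise
fragments bouts — but trial classification never uses that merging.
Speed samples between the two thresholds extend the preceding bout.

**VEI.** Per condition, the distance between the coherent F1 of the
observed trials and the mean coherent F1 of 100 ISI-shuffled versions; the
unit-level index is the mean over conditions (the sum is recorded
alongside), thresholded at 2 spikes/s. The coherent convention is essential
here: per-trial moduli of driven and shuffled trains both sit on the noise
floor and the threshold would separate nothing. Shuffles preserve the
first-spike latency per trial; the permutation count (100) is a package
default.

**Modulation index.** Ordinary least squares through the origin with
stationary means on the abscissa; `MI = slope − 1` exactly, computed
independently for F0 and F1. A symmetric alternative `(s−1)/(s+1)` exists
behind a flag. Units lacking ≥ 2 conditions with means in both states are
dropped and counted.

**Variability.** Fano in 50-ms bins, variance with the n−1 denominator,
zero-mean bins skipped (0/0 is undefined and contributes no information);
bins are averaged within condition, then conditions with equal weight,
within each state. ≥ 10 trials per condition are required.

**Correlations.** CCGs use 1-ms bins (fine enough to resolve monosynaptic
structure) over same-condition trials. The default corrector is the
all-pairs (PSTH/shuffle) predictor subtracted from the CCG *and* both
ACGs: with it, the total corrected CCG mass equals the count covariance
and the total ACG mass the count variance, so `r_CCG` at the full trial
window equals the Pearson correlation of whole-trial counts identically —
the convergence property that gives the statistic its meaning. The classic
one-trial shift predictor is available (`predictor="shift"`, CCG only,
ACGs raw) and agrees in expectation but not exactly. The timescale fit
uses the saturating form `A(1 − exp(−t/τ))`, consistent with convergence
to `r_SC`; series that do not saturate (final value below 80% of the
maximum) or whose τ falls below the first grid point are flagged
unreliable. Spike-count correlations are computed per condition
(≥ 10 trials, zero-variance conditions excluded and counted) in a 1-s
window starting 0.5 s after onset (a full-trial window is an option), with
a delete-one jackknife SE capped at 100 deletions, then averaged across
conditions.

**Tuning.** The two-Gaussian model is fitted on the log2-frequency axis —
conditions are octave-spaced and bandwidth is conventionally quoted in
octaves — with the spread shared between branches, bounded least squares,
and a multi-start grid (preferred frequency seeded at every tested
frequency × two spread seeds). Goodness is variance explained; the 0.9
inclusion threshold interprets "goodness of fit" as R². Bandwidth is the
FWHM above the larger baseline, clipped and flagged at the sampled domain
edges. Blank-condition F1 is reported alongside but never used as a fit
point.

**Cell typing.** SF features are the concatenated cycle averages (64
phase bins each, 2-ms-HWHM circular Gaussian smoothing, HWHM→σ via
`σ = HWHM/√(2 ln 2)`) over the five SF conditions plus blank, normalized to
the global peak; suppressed units (stimulus mean rate below blank mean)
are excluded beforehand. k-means uses Euclidean distance with 50 restarts
and a fixed seed; clusters are renumbered by descending (highest-SF segment
mean − blank segment mean), which pins the nonlinear high-SF cluster to
"Group 1" across runs — the stimulus-driven elevation, not the absolute
level, is what distinguishes that family from a flat high-baseline one.
For the ON/OFF classification, a half-cycle counts as driven when its
cycle-average peak exceeds the blank mean by 4 standard errors of a
cycle-average bin under a Poisson blank (`sqrt(μ/(w·C))`); the factor 4
(not 3) reflects that the peak is a maximum over ~32 bins, so 3 SE admits
a few percent of spurious both-half units while 4 SE admits ~0.1%. Units
driven in both halves are excluded as ON-OFF, units driven in neither are
unclassified; the remainder are partitioned by k-means (k = 4) on
peak-normalized cycle averages, and clusters are *named* by the polarity of
the driven half and a transience index (peak over last-quarter plateau;
within a polarity the higher-index cluster is transient) — the boundary is
decided by the clustering, the index only names the clusters.

## Verification protocols and problem sizes

`spikestate.protocols` packages the self-checks used by both the test
suite and `scripts/acceptance.py`. The sizes are chosen so each recovery
has comfortable statistical resolution: estimator fidelity at 200 trials
(the F1 estimator's SE is 0.22 spikes/s there, and assertions use 3 SE);
modulation recovery over 100 units at gain 1.3 with 30 stationary / 10
locomotion trials per condition, plus a 60-unit null-gain sign test;
responsiveness rates over 100 driven (broadly tuned, peak amplitude 4–10
spikes/s) and 100 rate-matched null units at 100 permutations; Fano
oracles at 200 (Poisson) and 400 (overdispersed) trials; the r_CCG
endpoint identity and jackknife coverage over 100 independent pairs of 40
trials; tuning recovery over 100 noisy fits at 40 trials per condition;
cell typing over 75-unit SF and 80-unit reversal populations with the
differential-modulation headline evaluated over 20 seeds; behavioral
calibration over ~10,000 bouts. The full battery runs in a few minutes on
one CPU.

## Known limitations

The pipeline analyzes one session at a time and does not pool across
sessions or animals; no errors-in-variables correction is applied to the
origin-constrained fit (noise in stationary means biases the slope
slightly toward zero at low trial counts); the per-trial-modulus F1 mean
is noise-floor-biased by construction and should not be read as an
amplitude estimate (use the coherent field); the shared-noise model has no
within-trial timescale, so correlation-timescale estimates on synthetic
data reflect the window geometry rather than a biophysical constant; and
the transient/sustained naming threshold (peak/plateau = 2) only matters
in the degenerate case where a polarity receives one or more than two
clusters.
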