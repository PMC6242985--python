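"""Ground-truth synthetic sessions: behavior, stimulus schedule, spike trains.

The generator emulates the structure of a head-fixed treadmill recording in
mouse early visual areas:

* a behavioral trace alternating locomotion and stationary bouts with
  log-normal durations (medians 6.4 s and 8.8 s), locomotion speed drawn
  from a gamma distribution matched to mean 13.6 / SD 11.9 cm/s, stationary
  speed below 0.25 cm/s, and an optional pupil-diameter channel that dilates
  quickly at locomotion onset and constricts slowly at offset;
* a shuffled-block stimulus schedule of 2-s trials separated by gray gaps:
  drifting gratings at five temporal frequencies (1-16 Hz) or five spatial
  frequencies (0.01-0.16 cpd) plus blanks, or full-field contrast reversal
  at 1 Hz;
* per-unit inhomogeneous-Poisson spike trains (global-envelope thinning)
  whose rate is a rectified sum of baseline and stimulus terms, multiplied
  by a behavioral gain (``loco_gain`` while the animal runs), a per-trial
  log-normal private gain (coefficient of variation ``gain_noise_cv``) and a
  per-trial shared gain common to all units with ``shared_noise_weight > 0``.

Cell classes map onto the functional taxonomy the downstream analyses are
meant to recover: linearly tuned units respond with a cosine at the drift
frequency whose amplitude follows the two-Gaussian tuning curve; nonlinear
high-SF units add a firing-rate elevation and a frequency-doubled component
at the two highest spatial frequencies; ON/OFF classes respond to contrast
reversal with half-wave exponential-decay cycle templates (transient decay
50 ms, sustained 400 ms); suppressed units have a negative stimulus term.

Everything is driven by a single integer seed; identical configurations
produce bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import BehaviorTrace, DegenerateSessionError, SpikeStateError, SpikeTrain, make_trial_table
from .tuning import two_gaussian

__all__ = [
    "SynthConfig",
    "UnitSpec",
    "SynthGroundTruth",
    "SimulatedSession",
    "generate_behavior",
    "generate_trials",
    "generate_spikes",
    "simulate_session",
    "make_sf_taxonomy",
    "make_onoff_population",
]

CELL_CLASSES = (
    "linear-tuned",
    "nonlinear-highSF",
    "transient-ON",
    "sustained-ON",
    "transient-OFF",
    "sustained-OFF",
    "ON-OFF",
    "suppressed",
)


class ThinningEnvelopeError(RuntimeError):
    """Instantaneous rate exceeded the thinning envelope (internal error)."""


@dataclass
class UnitSpec:
    """Ground-truth parameters of one synthetic unit.

    ``tuning`` holds the two-Gaussian parameters ``(p, a, s, b1, b2)`` that
    set the F1 amplitude of grating responses (p in Hz or cpd to match the
    experiment, s in octaves, amplitudes in spikes/s). ``loco_gain``
    multiplies the rate while the animal is in a locomotion bout.
    """

    unit_id: str
    baseline_rate: float = 5.0
    tuning: tuple[float, float, float, float, float] = (4.0, 10.0, 1.0, 1.0, 1.0)
    response_phase: float = 0.0
    loco_gain: float = 1.0
    cell_class: str = "linear-tuned"
    f2_weight: float = 0.0  # spikes/s; nonlinear-highSF only
    shared_noise_weight: float = 0.0
    gain_noise_cv: float = 0.0
    transient_tau: float = 0.05  # s, decay of the transient cycle template
    sustained_tau: float = 0.40  # s, decay of the sustained cycle template
    region: str = "dLGN"

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise SpikeStateError("baseline_rate must be >= 0")
        if self.loco_gain <= 0:
            raise SpikeStateError("loco_gain must be > 0")
        if self.f2_weight < 0:
            raise SpikeStateError("f2_weight must be >= 0")
        if self.cell_class not in CELL_CLASSES:
            raise SpikeStateError(f"unknown cell_class {self.cell_class!r}")


@dataclass
class SynthConfig:
    """Session-level generator settings (defaults follow the emulated assay)."""

    rng_seed: int = 0
    session_length: float = 720.0  # s; ~40 repeats/condition in a TF session
    loco_bout_median: float = 6.4  # s
    stat_bout_median: float = 8.8  # s
    bout_lognorm_sigma: float = 0.8
    speed_mean: float = 13.6  # cm/s, inside locomotion bouts
    speed_sd: float = 11.9  # cm/s
    trial_duration: float = 2.0  # s
    gray_gap: float = 1.0  # s
    tf_set: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)  # Hz
    sf_set: tuple[float, ...] = (0.01, 0.02, 0.04, 0.08, 0.16)  # cpd
    sf_drift_tf: float = 2.0  # Hz, drift rate used in SF sessions
    cr_freq: float = 1.0  # Hz, contrast-reversal rate
    sample_rate: float = 60.0  # Hz, behavior trace sampling
    unit_specs: tuple[UnitSpec, ...] = ()

    def __post_init__(self) -> None:
        positive = (
            self.session_length, self.loco_bout_median, self.stat_bout_median,
            self.speed_mean, self.speed_sd, self.trial_duration,
            self.sf_drift_tf, self.cr_freq, self.sample_rate,
        )
        if any(v <= 0 for v in positive) or self.gray_gap < 0 or self.bout_lognorm_sigma < 0:
            raise SpikeStateError("config durations and rates must be positive")
        for s in (self.tf_set, self.sf_set):
            if np.any(np.diff(s) <= 0):
                raise SpikeStateError("tf_set/sf_set must be strictly increasing")
        self.unit_specs = tuple(self.unit_specs)

    @property
    def n_units(self) -> int:
        return len(self.unit_specs)


@dataclass
class SynthGroundTruth:
    """Hidden generator state used by recovery tests."""

    units: tuple[UnitSpec, ...]
    bouts: pd.DataFrame  # columns start, stop, state
    shared_draws: np.ndarray  # one standard-normal draw per trial
    trial_gains: dict[str, np.ndarray]  # unit_id -> realized per-trial gain noise

    def spec(self, unit_id: str) -> UnitSpec:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


@dataclass
class SimulatedSession:
    trace: BehaviorTrace
    bouts: pd.DataFrame
    trials: pd.DataFrame
    trains: list[SpikeTrain]
    ground_truth: SynthGroundTruth


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams keyed by (seed, stage)
    return np.random.default_rng(np.random.SeedSequence((int(config.rng_seed), stream)))


# ---------------------------------------------------------------------------
# behavior


def _sample_bouts(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    T = config.session_length
    state = int(rng.integers(2))  # 1 = locomotion
    starts: list[float] = []
    stops: list[float] = []
    labels: list[str] = []
    t = 0.0
    first = True
    while t < T:
        median = config.loco_bout_median if state else config.stat_bout_median
        if config.bout_lognorm_sigma == 0:
            d = median
        else:
            d = float(rng.lognormal(np.log(median), config.bout_lognorm_sigma))
        if first and d >= T:
            raise DegenerateSessionError(
                f"session of {T} s is shorter than the first bout ({d:.1f} s)"
            )
        first = False
        starts.append(t)
        stops.append(min(t + d, T))
        labels.append("locomotion" if state else "stationary")
        t += d
        state ^= 1
    return pd.DataFrame({"start": starts, "stop": stops, "state": labels})


def generate_behavior(
    config: SynthConfig, with_pupil: bool = True
) -> tuple[BehaviorTrace, pd.DataFrame]:
    """Simulate the treadmill-speed (and pupil) trace.

    Returns the trace together with the ground-truth bout table
    (``start, stop, state``); the bouts tile ``[0, session_length)``.
    """
    rng = _rng(config, 0)
    bouts = _sample_bouts(config, rng)
    # uniform sampling covering the closed interval [0, session_length] so
    # the trace spans every trial and spike the session can contain
    n_steps = int(round(config.session_length * config.sample_rate))
    times = np.linspace(0.0, config.session_length, n_steps + 1)
    n = times.size

    # gamma matched to the configured locomotion-speed moments
    shape = (config.speed_mean / config.speed_sd) ** 2
    scale = config.speed_sd**2 / config.speed_mean

    starts = bouts["start"].to_numpy()
    idx = np.searchsorted(starts, times, side="right") - 1
    is_loco = bouts["state"].to_numpy()[idx] == "locomotion"

    speed = np.empty(n)
    speed[~is_loco] = rng.uniform(0.0, 0.2, size=int((~is_loco).sum()))
    speed[is_loco] = rng.gamma(shape, scale, size=int(is_loco.sum()))
    # light smoothing within each locomotion bout (speed is not white noise)
    for _, b in bouts[bouts["state"] == "locomotion"].iterrows():
        sl = slice(*np.searchsorted(times, [b["start"], b["stop"]]))
        if sl.stop - sl.start >= 3:
            speed[sl] = uniform_filter1d(speed[sl], size=3, mode="nearest")

    pupil = None
    if with_pupil:
        pupil = np.empty(n)
        level = 1.6  # mm, stationary baseline
        for _, b in bouts.iterrows():
            sl = slice(*np.searchsorted(times, [b["start"], b["stop"]]))
            if sl.stop <= sl.start:
                continue
            loco = b["state"] == "locomotion"
            target = 2.3 if loco else 1.6
            tau = 0.7 if loco else 2.5  # fast dilation, slow constriction
            tl = times[sl] - times[sl.start]
            seg = target + (level - target) * np.exp(-tl / tau)
            pupil[sl] = seg
            level = float(seg[-1])
        pupil = pupil + rng.normal(0.0, 0.02, size=n)

    return BehaviorTrace(times, speed, pupil), bouts


# ---------------------------------------------------------------------------
# trials


def generate_trials(config: SynthConfig, experiment: str) -> pd.DataFrame:
    """Shuffled-block stimulus schedule for a ``tf``, ``sf`` or ``cr`` session."""
    rng = _rng(config, 1)
    if experiment == "tf":
        conds = [("tf_grating", f) for f in config.tf_set] + [("blank", np.nan)]
    elif experiment == "sf":
        conds = [("sf_grating", c) for c in config.sf_set] + [("blank", np.nan)]
    elif experiment == "cr":
        # three reversal trials per blank keeps cycle counts high
        conds = [("contrast_reversal", config.cr_freq)] * 3 + [("blank", np.nan)]
    else:
        raise SpikeStateError(f"unknown experiment {experiment!r}; use tf, sf or cr")

    period = config.trial_duration + config.gray_gap
    block_len = len(conds) * period
    n_blocks = int(config.session_length // block_len)
    if n_blocks < 1:
        raise SpikeStateError("session too short for one stimulus block")

    onsets, classes, params = [], [], []
    for b in range(n_blocks):
        order = rng.permutation(len(conds))
        for i, ci in enumerate(order):
            onsets.append(b * block_len + i * period)
            classes.append(conds[ci][0])
            params.append(conds[ci][1])
    return make_trial_table(
        np.array(onsets), np.full(len(onsets), config.trial_duration),
        np.array(classes, dtype=object), np.array(params),
    )


# ---------------------------------------------------------------------------
# spikes


def _stimulus_terms(
    spec: UnitSpec, trials: pd.DataFrame, config: SynthConfig
) -> dict[str, np.ndarray]:
    """Per-trial (amplitude, DC, F2, template) descriptors for one unit."""
    n = len(trials)
    cls = trials["stimulus_class"].to_numpy()
    par = trials["parameter"].to_numpy(dtype=float)

    A = np.zeros(n)  # cosine (F1) amplitude, spikes/s
    dc = np.zeros(n)  # stimulus-driven rate offset (can be negative)
    f2 = np.zeros(n)  # frequency-doubled amplitude
    f = np.zeros(n)  # drift/modulation frequency, Hz
    t_on = np.zeros(n)  # ON half-cycle template amplitude
    t_off = np.zeros(n)  # OFF half-cycle template amplitude

    grating = np.isin(cls, ("tf_grating", "sf_grating"))
    if grating.any() and spec.cell_class != "suppressed":
        A[grating] = np.maximum(0.0, two_gaussian(par[grating], *spec.tuning))
        f[grating] = np.where(cls[grating] == "tf_grating", par[grating], config.sf_drift_tf)
    if spec.cell_class == "suppressed" and grating.any():
        dc[grating] = -spec.tuning[1]
        A[grating] = 0.0
    if spec.cell_class == "nonlinear-highSF":
        top2 = set(sorted(config.sf_set)[-2:])
        hi = (cls == "sf_grating") & np.isin(par, list(top2))
        dc[hi] += spec.f2_weight
        f2[hi] = spec.f2_weight

    rev = cls == "contrast_reversal"
    if rev.any():
        f[rev] = par[rev]
        amp = spec.tuning[1]
        if spec.cell_class in ("transient-ON", "sustained-ON"):
            t_on[rev] = amp
        elif spec.cell_class in ("transient-OFF", "sustained-OFF"):
            t_off[rev] = amp
        elif spec.cell_class == "ON-OFF":
            t_on[rev] = amp
            t_off[rev] = amp
    return {"A": A, "dc": dc, "f2": f2, "f": f, "t_on": t_on, "t_off": t_off}


def generate_spikes(
    config: SynthConfig, trials: pd.DataFrame, bouts: pd.DataFrame
) -> tuple[list[SpikeTrain], SynthGroundTruth]:
    """Draw one inhomogeneous-Poisson spike train per configured unit.

    Thinning uses a single global rate envelope per unit; if the realized
    rate ever exceeds the envelope an internal error is raised (the envelope
    is never silently clipped).
    """
    if not config.unit_specs:
        raise SpikeStateError("config.unit_specs is empty")
    rng = _rng(config, 2)
    T = config.session_length
    n_trials = len(trials)
    onsets = trials["onset"].to_numpy(dtype=float)
    durs = trials["duration"].to_numpy(dtype=float)
    if n_trials and onsets[-1] + durs[-1] > T + 1e-9:
        raise SpikeStateError("trials extend beyond the session span")

    loco = bouts[bouts["state"] == "locomotion"]
    loco_start = loco["start"].to_numpy(dtype=float)
    loco_stop = loco["stop"].to_numpy(dtype=float)

    shared_z = rng.normal(size=n_trials)
    trains: list[SpikeTrain] = []
    trial_gains: dict[str, np.ndarray] = {}

    for spec in config.unit_specs:
        # per-trial multiplicative gain noise (mean 1 by construction)
        gain = np.ones(n_trials)
        if spec.gain_noise_cv > 0:
            sg = np.sqrt(np.log1p(spec.gain_noise_cv**2))
            gain *= np.exp(sg * rng.normal(size=n_trials) - sg**2 / 2)
        else:
            rng.normal(size=n_trials)  # keep stream alignment across specs
        if spec.shared_noise_weight > 0:
            w = spec.shared_noise_weight
            gain *= np.exp(w * shared_z - w**2 / 2)
        trial_gains[spec.unit_id] = gain

        terms = _stimulus_terms(spec, trials, config)
        smax = (
            terms["A"] + np.maximum(0.0, terms["dc"]) + terms["f2"]
            + np.maximum(terms["t_on"], terms["t_off"])
        )
        gmax = max(1.0, spec.loco_gain)
        peak = gmax * np.max(gain * (spec.baseline_rate + smax), initial=0.0)
        envelope = max(peak, gmax * spec.baseline_rate)
        if envelope <= 0:
            trains.append(SpikeTrain(spec.unit_id, np.empty(0), T, spec.region))
            continue

        n_cand = rng.poisson(envelope * T)
        t = np.sort(rng.uniform(0.0, T, size=n_cand))
        u = rng.uniform(0.0, 1.0, size=n_cand)

        idx = np.searchsorted(onsets, t, side="right") - 1
        idx_c = np.clip(idx, 0, max(n_trials - 1, 0))
        rel = t - onsets[idx_c]
        in_trial = (idx >= 0) & (rel < durs[idx_c]) if n_trials else np.zeros(t.size, bool)

        stim = np.zeros(t.size)
        if in_trial.any():
            j = idx_c[in_trial]
            tr = rel[in_trial]
            ph = spec.response_phase
            fj = terms["f"][j]
            s = terms["A"][j] * np.cos(2 * np.pi * fj * tr - ph) + terms["dc"][j]
            s += terms["f2"][j] * np.cos(4 * np.pi * fj * tr - 2 * ph)
            tmpl = (terms["t_on"][j] > 0) | (terms["t_off"][j] > 0)
            if tmpl.any():
                cyc = 1.0 / fj[tmpl]
                phase = np.mod(tr[tmpl], cyc)
                half = cyc / 2
                tau = (
                    spec.transient_tau
                    if spec.cell_class.startswith("transient") or spec.cell_class == "ON-OFF"
                    else spec.sustained_tau
                )
                on = phase < half
                add = np.where(
                    on,
                    terms["t_on"][j][tmpl] * np.exp(-phase / tau),
                    terms["t_off"][j][tmpl] * np.exp(-(phase - half) / tau),
                )
                s[tmpl] += add
            stim[in_trial] = s

        g = np.ones(t.size)
        if loco_start.size:
            k = np.searchsorted(loco_start, t, side="right") - 1
            kc = np.clip(k, 0, loco_start.size - 1)
            running = (k >= 0) & (t < loco_stop[kc])
            g[running] = spec.loco_gain
        g[in_trial] *= trial_gains[spec.unit_id][idx_c[in_trial]]

        rate = g * np.maximum(0.0, spec.baseline_rate + stim)
        if np.any(rate > envelope * (1 + 1e-9)):
            raise ThinningEnvelopeError(
                f"unit {spec.unit_id}: rate exceeded thinning envelope"
            )
        spikes = t[u < rate / envelope]
        trains.append(SpikeTrain(spec.unit_id, spikes, T, spec.region))

    gt = SynthGroundTruth(
        units=config.unit_specs, bouts=bouts, shared_draws=shared_z, trial_gains=trial_gains
    )
    return trains, gt


def simulate_session(
    config: SynthConfig, experiment: str, with_pupil: bool = True
) -> SimulatedSession:
    """Behavior + schedule + spikes for one session, fully seeded."""
    trace, bouts = generate_behavior(config, with_pupil=with_pupil)
    trials = generate_trials(config, experiment)
    trains, gt = generate_spikes(config, trials, bouts)
    return SimulatedSession(trace, bouts, trials, trains, gt)


# ---------------------------------------------------------------------------
# canned populations implementing the functional taxonomy


def _jitter(rng: np.random.Generator, value: float, frac: float = 0.15) -> float:
    return float(value * rng.uniform(1 - frac, 1 + frac))


def make_sf_taxonomy(
    rng: np.random.Generator,
    n_nonlinear: int = 25,
    n_tuned: int = 25,
    n_highbase: int = 25,
    gains: tuple[float, float, float] = (1.0, 1.0, 1.0),
    gain_noise_cv: float = 0.1,
) -> tuple[list[UnitSpec], dict[str, int]]:
    """Three SF-response families: nonlinear high-SF, mid-SF tuned, high baseline.

    Returns the specs and a ground-truth family label per unit (0, 1, 2 in
    the order above).
    """
    specs: list[UnitSpec] = []
    labels: dict[str, int] = {}
    for i in range(n_nonlinear):
        uid = f"nl{i:03d}"
        specs.append(UnitSpec(
            unit_id=uid,
            baseline_rate=_jitter(rng, 5.0),
            tuning=(0.02, _jitter(rng, 4.0), 1.0, 1.0, 0.5),
            response_phase=float(rng.uniform(0, 2 * np.pi)),
            loco_gain=gains[0],
            cell_class="nonlinear-highSF",
            f2_weight=_jitter(rng, 9.0),
            gain_noise_cv=gain_noise_cv,
        ))
        labels[uid] = 0
    for i in range(n_tuned):
        uid = f"ln{i:03d}"
        specs.append(UnitSpec(
            unit_id=uid,
            baseline_rate=_jitter(rng, 2.0),
            tuning=(_jitter(rng, 0.04, 0.3), _jitter(rng, 14.0), 1.0, 1.0, 1.0),
            response_phase=float(rng.uniform(0, 2 * np.pi)),
            loco_gain=gains[1],
            cell_class="linear-tuned",
            gain_noise_cv=gain_noise_cv,
        ))
        labels[uid] = 1
    for i in range(n_highbase):
        uid = f"hb{i:03d}"
        specs.append(UnitSpec(
            unit_id=uid,
            baseline_rate=_jitter(rng, 16.0),
            tuning=(0.02, _jitter(rng, 4.0), 1.5, 2.0, 2.0),
            response_phase=float(rng.uniform(0, 2 * np.pi)),
            loco_gain=gains[2],
            cell_class="linear-tuned",
            gain_noise_cv=gain_noise_cv,
        ))
        labels[uid] = 2
    return specs, labels


def make_onoff_population(
    rng: np.random.Generator,
    n_per_class: int = 20,
    gains: dict[str, float] | None = None,
    gain_noise_cv: float = 0.1,
) -> tuple[list[UnitSpec], dict[str, str]]:
    """Transient/sustained ON/OFF units for contrast-reversal sessions."""
    gains = gains or {}
    specs: list[UnitSpec] = []
    labels: dict[str, str] = {}
    for cls in ("transient-ON", "sustained-ON", "transient-OFF", "sustained-OFF"):
        for i in range(n_per_class):
            uid = f"{cls.replace('-', '')}{i:03d}"
            specs.append(UnitSpec(
                unit_id=uid,
                baseline_rate=_jitter(rng, 2.5),
                tuning=(0.04, _jitter(rng, 24.0), 1.0, 1.0, 1.0),
                loco_gain=gains.get(cls, 1.0),
                cell_class=cls,
                gain_noise_cv=gain_noise_cv,
            ))
            labels[uid] = cls
    return specs, labels
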