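"""Per-trial and per-condition F0/F1 response statistics.

F0 is the mean firing rate over the analyzed window. F1 is the amplitude of
the firing-rate component at the stimulus temporal frequency, estimated per
trial from the spike times as

    F1 = | (2 / T) * sum_k exp(-i 2 pi f (t_k - onset)) |

so that a rate ``b + A cos(2 pi f t)`` yields amplitude ``A`` (peak, not
peak-to-peak). Windows are truncated to a whole number of stimulus cycles.
Per-trial amplitudes are averaged across trials (modulus first, then mean),
which keeps a per-trial scalar available for variability analyses and makes
the mean robust to phase drift. The modulus of a finite-count trial carries
a positive noise floor (a homogeneous-Poisson train has E|F1| > 0), which
the ISI-permutation null estimates and the normalized F1 divides out; the
phase-coherent estimate ``|mean complex F1|``, which averages that noise
away, is reported alongside as ``f1_vector`` and is the estimator of choice
when the amplitude itself is the quantity of interest.

The null for temporal locking permutes the order of each trial's inter-spike
intervals: spike count, first-spike latency and the ISI multiset are
preserved while the locking to the stimulus is destroyed. The visual-evoked
index (VEI) is the mean over stimulus conditions of the distance between the
observed and ISI-permuted mean F1 amplitudes; units with VEI > 2.0 spikes/s
count as visually responsive. Normalized F1 is the ratio of observed to
permuted F1 (~1 for an unlocked train).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import SpikeStateError, SpikeTrain, condition_key

__all__ = [
    "ResponseSummary",
    "CycleAverage",
    "VEIResult",
    "per_trial_f0_f1",
    "permute_isi",
    "trial_f1_amplitudes",
    "permuted_f1_amplitudes",
    "visual_evoked_index",
    "normalized_f1",
    "condition_summary",
    "cycle_average",
]

VEI_THRESHOLD = 2.0  # spikes/s
N_PERM = 100

#: Gaussian kernel half-width-at-half-maximum used for cycle averages (s)
CYCLE_KERNEL_HWHM = 0.002


def _analysis_window(onset: float, duration: float, freq: float) -> float:
    """Largest whole-cycle duration from onset (equals duration when exact)."""
    if freq <= 0:
        raise SpikeStateError("stimulus frequency must be positive")
    n_cycles = np.floor(duration * freq + 1e-9)
    if n_cycles < 1:
        raise SpikeStateError("trial shorter than one stimulus cycle")
    return float(n_cycles / freq)


def per_trial_f0_f1(
    train: SpikeTrain, onset: float, duration: float, freq: float
) -> tuple[float, complex]:
    """F0 (spikes/s) and the complex F1 component for one trial."""
    T = _analysis_window(onset, duration, freq)
    t = train.in_window(onset, onset + T)
    f0 = t.size / T
    f1 = (2.0 / T) * np.sum(np.exp(-2j * np.pi * freq * (t - onset)))
    return float(f0), complex(f1)


def permute_isi(spikes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle the order of a trial's inter-spike intervals.

    The first-spike latency, the spike count and the multiset of ISIs are
    preserved exactly; trains with 0 or 1 spikes are returned unchanged.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 2:
        return spikes.copy()
    isis = np.diff(spikes)
    return spikes[0] + np.concatenate(([0.0], np.cumsum(rng.permutation(isis))))


def trial_f1_amplitudes(
    train: SpikeTrain, trials: pd.DataFrame, freq_of: "callable"
) -> np.ndarray:
    """Per-trial |F1| (spikes/s) for every row of ``trials``."""
    out = np.empty(len(trials))
    for k, (_, row) in enumerate(trials.iterrows()):
        f = freq_of(row)
        _, c = per_trial_f0_f1(train, row["onset"], row["duration"], f)
        out[k] = abs(c)
    return out


def _f1_amp_from_spikes(rel_times: np.ndarray, T: float, freq: float) -> float:
    return abs((2.0 / T) * np.sum(np.exp(-2j * np.pi * freq * rel_times)))


def permuted_f1_components(
    train: SpikeTrain,
    trials: pd.DataFrame,
    freq_of: "callable",
    rng: np.random.Generator,
    n_perm: int = N_PERM,
) -> np.ndarray:
    """Complex F1 of ISI-permuted trains, shape (n_perm, n_trials).

    Permutations are vectorised per trial: the ISI multiset is shuffled
    ``n_perm`` times and the complex F1 of each shuffle returned.
    """
    out = np.empty((n_perm, len(trials)), dtype=complex)
    for k, (_, row) in enumerate(trials.iterrows()):
        f = freq_of(row)
        T = _analysis_window(row["onset"], row["duration"], f)
        t = train.in_window(row["onset"], row["onset"] + T) - row["onset"]
        if t.size < 2:
            out[:, k] = (2.0 / T) * np.sum(np.exp(-2j * np.pi * f * t))
            continue
        isis = np.tile(np.diff(t), (n_perm, 1))
        isis = rng.permuted(isis, axis=1)
        times = t[0] + np.concatenate(
            (np.zeros((n_perm, 1)), np.cumsum(isis, axis=1)), axis=1
        )
        out[:, k] = (2.0 / T) * np.sum(np.exp(-2j * np.pi * f * times), axis=1)
    return out


def permuted_f1_amplitudes(
    train: SpikeTrain,
    trials: pd.DataFrame,
    freq_of: "callable",
    rng: np.random.Generator,
    n_perm: int = N_PERM,
) -> np.ndarray:
    """Mean |F1| over ``n_perm`` ISI permutations, per trial."""
    comp = permuted_f1_components(train, trials, freq_of, rng, n_perm)
    return np.abs(comp).mean(axis=0)


def default_freq_of(row: pd.Series, sf_drift_tf: float = 2.0) -> float:
    """Stimulus temporal frequency for a trial row.

    TF gratings and contrast reversal carry their rate in ``parameter``; SF
    gratings drift at ``sf_drift_tf``; blanks are analyzed at the session's
    drift rate so that a noise-floor F1 is still defined.
    """
    cls = row["stimulus_class"]
    if cls == "tf_grating" or cls == "contrast_reversal":
        return float(row["parameter"])
    return float(sf_drift_tf)


@dataclass
class VEIResult:
    """Visual-evoked index of one unit."""

    unit_id: str
    vei: float  # mean over conditions of |mean F1 - mean permuted F1|
    vei_sum: float  # sum over conditions of the same distances
    per_condition: dict[str, float]
    responsive: bool
    incomplete: bool = False  # True when some conditions were missing


def visual_evoked_index(
    train: SpikeTrain,
    trials: pd.DataFrame,
    *,
    rng: np.random.Generator,
    n_perm: int = N_PERM,
    sf_drift_tf: float = 2.0,
    threshold: float = VEI_THRESHOLD,
    min_trials: int = 5,
) -> VEIResult:
    """Responsiveness statistic from ISI-permutation nulls.

    Per stimulus condition (blanks excluded) the mean response amplitude is
    the phase-coherent ``|mean complex F1|`` across trials -- averaging the
    complex components first cancels the finite-count noise floor that a
    per-trial modulus would retain. The permuted counterpart applies the
    same estimator to each set of ISI-shuffled trains and averages over
    permutations. The VEI is the mean over conditions of the distances
    between the two, and the unit is flagged responsive when it exceeds
    ``threshold`` (spikes/s).
    """
    stim = trials[trials["stimulus_class"] != "blank"]
    if stim.empty:
        raise SpikeStateError("no stimulus trials for VEI")
    freq_of = lambda row: default_freq_of(row, sf_drift_tf)
    distances: dict[str, float] = {}
    incomplete = False
    for cond, sub in stim.groupby(condition_key(stim)):
        if len(sub) < min_trials:
            incomplete = True
            continue
        comps = np.empty(len(sub), dtype=complex)
        for k, (_, row) in enumerate(sub.iterrows()):
            _, comps[k] = per_trial_f0_f1(train, row["onset"], row["duration"], freq_of(row))
        obs = abs(comps.mean())
        perm_matrix = permuted_f1_components(train, sub, freq_of, rng, n_perm)
        perm = float(np.abs(perm_matrix.mean(axis=1)).mean())
        distances[cond] = float(abs(obs - perm))
    if not distances:
        raise SpikeStateError("no condition reached the minimum trial count")
    vals = np.array(list(distances.values()))
    vei = float(vals.mean())
    return VEIResult(
        unit_id=train.unit_id,
        vei=vei,
        vei_sum=float(vals.sum()),
        per_condition=distances,
        responsive=vei > threshold,
        incomplete=incomplete,
    )


@dataclass
class ResponseSummary:
    """Per unit x condition x state F0/F1 statistics."""

    unit_id: str
    condition: str
    stimulus_class: str
    parameter: float
    state: str
    n_trials: int
    f0: float  # spikes/s
    f1_amp: float  # mean per-trial |F1|, spikes/s
    f1_vector: float  # |mean complex F1| across trials, spikes/s
    f1_phase: float  # circular mean phase, radians
    per_trial_f1: np.ndarray = field(repr=False, default=None)
    per_trial_f0: np.ndarray = field(repr=False, default=None)
    f1_permuted: float = float("nan")
    normalized_f1: float = float("nan")


def normalized_f1(f1_amp: float, f1_permuted: float) -> float:
    """Observed over ISI-permuted F1 amplitude (~1 for an unlocked train)."""
    if not f1_permuted > 0:
        raise SpikeStateError("normalized F1 undefined: permuted F1 is zero")
    return float(f1_amp / f1_permuted)


def condition_summary(
    train: SpikeTrain,
    trials: pd.DataFrame,
    *,
    state: str = "all",
    min_trials: int = 1,
    sf_drift_tf: float = 2.0,
    rng: np.random.Generator | None = None,
    n_perm: int = N_PERM,
) -> list[ResponseSummary]:
    """Aggregate F0/F1 across trials of each condition in one state.

    Conditions with fewer than ``min_trials`` trials are omitted. When an
    ``rng`` is given, the ISI-permutation mean F1 and the normalized F1 are
    filled in as well.
    """
    sub = trials if state == "all" else trials[trials["state"] == state]
    out: list[ResponseSummary] = []
    if sub.empty:
        return out
    freq_of = lambda row: default_freq_of(row, sf_drift_tf)
    for cond, grp in sub.groupby(condition_key(sub), sort=True):
        if len(grp) < min_trials:
            continue
        f0s = np.empty(len(grp))
        f1c = np.empty(len(grp), dtype=complex)
        for k, (_, row) in enumerate(grp.iterrows()):
            f0s[k], f1c[k] = per_trial_f0_f1(
                train, row["onset"], row["duration"], freq_of(row)
            )
        amps = np.abs(f1c)
        summ = ResponseSummary(
            unit_id=train.unit_id,
            condition=cond,
            stimulus_class=str(grp["stimulus_class"].iloc[0]),
            parameter=float(grp["parameter"].iloc[0]),
            state=state,
            n_trials=len(grp),
            f0=float(f0s.mean()),
            f1_amp=float(amps.mean()),
            f1_vector=float(abs(f1c.mean())),
            f1_phase=float(np.angle(np.sum(f1c))),
            per_trial_f1=amps,
            per_trial_f0=f0s,
        )
        if rng is not None:
            perm = permuted_f1_amplitudes(train, grp, freq_of, rng, n_perm)
            summ.f1_permuted = float(perm.mean())
            if summ.f1_permuted > 0:
                summ.normalized_f1 = summ.f1_amp / summ.f1_permuted
        out.append(summ)
    return out


def summaries_to_frame(summaries: list[ResponseSummary]) -> pd.DataFrame:
    """Tabular view (one row per unit x condition x state)."""
    return pd.DataFrame(
        [
            {
                "unit_id": s.unit_id,
                "condition": s.condition,
                "stimulus_class": s.stimulus_class,
                "parameter": s.parameter,
                "state": s.state,
                "n_trials": s.n_trials,
                "F0": s.f0,
                "F1_amp": s.f1_amp,
                "F1_vector": s.f1_vector,
                "F1_phase": s.f1_phase,
                "F1_perm": s.f1_permuted,
                "norm_F1": s.normalized_f1,
            }
            for s in summaries
        ]
    )


@dataclass
class CycleAverage:
    """Firing rate folded over one stimulus cycle (phase histogram)."""

    unit_id: str
    condition: str
    state: str
    cycle_freq: float  # Hz
    edges: np.ndarray  # phase bin edges in [0, 1], length n_bins + 1
    rate: np.ndarray  # spikes/s per bin, smoothed
    n_cycles: int
    kernel_hwhm: float  # s


def cycle_average(
    train: SpikeTrain,
    trials: pd.DataFrame,
    cycle_freq: float,
    *,
    n_bins: int = 64,
    kernel_hwhm: float = CYCLE_KERNEL_HWHM,
    state: str = "all",
    condition: str = "",
) -> CycleAverage:
    """Fold spikes by stimulus phase and smooth circularly.

    The Gaussian kernel's half-width-at-half-maximum is ``kernel_hwhm``
    seconds (sigma = hwhm / sqrt(2 ln 2)); smoothing is circular over the
    cycle and conserves total spike count.
    """
    if cycle_freq <= 0:
        raise SpikeStateError("cycle_freq must be positive")
    if trials.empty:
        raise SpikeStateError("cycle average needs >= 1 trial")
    period = 1.0 / cycle_freq
    counts = np.zeros(n_bins)
    n_cycles = 0
    for _, row in trials.iterrows():
        T = _analysis_window(row["onset"], row["duration"], cycle_freq)
        t = train.in_window(row["onset"], row["onset"] + T) - row["onset"]
        phase = np.mod(t, period) / period
        counts += np.histogram(phase, bins=n_bins, range=(0.0, 1.0))[0]
        n_cycles += int(round(T / period))
    bin_dur = period / n_bins
    rate = counts / (n_cycles * bin_dur)
    sigma_bins = (kernel_hwhm / np.sqrt(2 * np.log(2))) / bin_dur
    if sigma_bins > 0:
        rate = gaussian_filter1d(rate, sigma_bins, mode="wrap")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return CycleAverage(
        unit_id=train.unit_id,
        condition=condition,
        state=state,
        cycle_freq=cycle_freq,
        edges=edges,
        rate=rate,
        n_cycles=n_cycles,
        kernel_hwhm=kernel_hwhm,
    )
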