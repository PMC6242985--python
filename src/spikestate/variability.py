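"""Trial-to-trial variability: Fano factor and F1 variance / CV per state.

The Fano factor is computed on spike counts in 50-ms bins across repeated
trials of one condition: per bin, variance over trials divided by mean over
trials (bins with zero mean are skipped), then averaged over bins; condition
results are averaged with equal weight. A Poisson process gives 1 at any bin
width; a doubly-stochastic (shared-gain) process exceeds 1 by ``cv**2 *
mean count`` per bin. Longer-time-scale variability uses the across-trial
variance of the per-trial F1 amplitude and its coefficient of variation.
All variances use the n-1 denominator; analyses require >= 10 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeStateError, SpikeTrain

__all__ = ["VariabilityResult", "fano_factor", "f1_variability", "trial_counts"]

FANO_BIN = 0.050  # s
MIN_TRIALS = 10


def trial_counts(
    train: SpikeTrain, onsets: np.ndarray, duration: float, bin_width: float
) -> np.ndarray:
    """Spike-count matrix (n_trials, n_bins) in fixed bins from each onset."""
    n_bins = int(round(duration / bin_width))
    if n_bins < 1:
        raise SpikeStateError("trial shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_width
    out = np.empty((len(onsets), n_bins))
    for i, on in enumerate(onsets):
        t = train.in_window(on, on + n_bins * bin_width) - on
        out[i] = np.histogram(t, bins=edges)[0]
    return out


def fano_factor(
    train: SpikeTrain,
    trials: pd.DataFrame,
    *,
    bin_width: float = FANO_BIN,
    min_trials: int = MIN_TRIALS,
) -> float:
    """Mean variance-to-mean ratio of binned counts for one condition+state.

    ``trials`` must all share one condition; fewer than ``min_trials`` rows
    raises. Returns NaN when every bin has zero mean.
    """
    if len(trials) < min_trials:
        raise SpikeStateError(f"Fano factor needs >= {min_trials} trials")
    dur = float(trials["duration"].min())
    counts = trial_counts(train, trials["onset"].to_numpy(), dur, bin_width)
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    ok = mean > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(var[ok] / mean[ok]))


def f1_variability(per_trial_f1: np.ndarray, min_trials: int = MIN_TRIALS) -> tuple[float, float]:
    """Across-trial variance and CV of the per-trial F1 amplitude.

    Returns ``(variance, cv)``; the CV is NaN when the mean is zero.
    """
    f1 = np.asarray(per_trial_f1, dtype=float)
    if f1.size < min_trials:
        raise SpikeStateError(f"F1 variability needs >= {min_trials} trials")
    var = float(f1.var(ddof=1))
    mean = float(f1.mean())
    cv = float(np.sqrt(var) / mean) if mean > 0 else float("nan")
    return var, cv


@dataclass
class VariabilityResult:
    """Condition-averaged variability measures of one unit in one state."""

    unit_id: str
    state: str
    fano: float
    f1_variance: float
    f1_cv: float
    n_conditions: int


def unit_variability(
    train: SpikeTrain,
    trials: pd.DataFrame,
    per_trial_f1_by_condition: dict[str, np.ndarray],
    *,
    state: str,
    bin_width: float = FANO_BIN,
    min_trials: int = MIN_TRIALS,
) -> VariabilityResult | None:
    """Equal-weight average of the per-condition measures for one unit.

    ``trials`` is the labeled trial table; only stimulus conditions with at
    least ``min_trials`` trials in ``state`` contribute. Returns None when
    no condition qualifies.
    """
    from .core import condition_key

    sub = trials[(trials["state"] == state) & (trials["stimulus_class"] != "blank")]
    fanos, f1vars, f1cvs = [], [], []
    for cond, grp in sub.groupby(condition_key(sub)):
        if len(grp) < min_trials:
            continue
        fanos.append(fano_factor(train, grp, bin_width=bin_width, min_trials=min_trials))
        if cond in per_trial_f1_by_condition:
            v, c = f1_variability(per_trial_f1_by_condition[cond], min_trials)
            f1vars.append(v)
            f1cvs.append(c)
    if not fanos:
        return None
    return VariabilityResult(
        unit_id=train.unit_id,
        state=state,
        fano=float(np.nanmean(fanos)),
        f1_variance=float(np.nanmean(f1vars)) if f1vars else float("nan"),
        f1_cv=float(np.nanmean(f1cvs)) if f1cvs else float("nan"),
        n_conditions=len(fanos),
    )
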