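"""Pairwise spike-train correlations: corrected CCGs, r_CCG and r_SC.

The cross-correlogram (CCG) of a pair is computed trial-by-trial at 1-ms
resolution over same-condition trials and corrected by subtracting a
stimulus predictor. The windowed, normalized correlogram integral

    r_CCG(t) = sum_{|tau| <= t} CCG(tau)
               / sqrt( sum_{|tau| <= t} ACG1(tau) * sum_{|tau| <= t} ACG2(tau) )

rises with the window half-width t and converges to the spike-count
correlation over whole-trial counts; the timescale of that saturation (an
exponential fit) is the pair's correlation integration time.

Two stimulus predictors are available. The default, ``"shuffle"``, is the
all-pairs (PSTH) predictor applied to the CCG *and* both ACGs; with it the
total corrected CCG mass equals the count covariance and the total ACG mass
the count variance, so r_CCG evaluated at the full trial window equals the
Pearson correlation of whole-trial spike counts exactly. ``"shift"`` is the
classic one-trial shift predictor (applied to the CCG only, ACGs left raw);
it converges to the same quantity in expectation but not identically.

Spike-count correlations (r_SC) are Pearson correlations of per-trial counts
in a fixed window (default 1 s starting 0.5 s after stimulus onset),
computed per condition with at least 10 trials, with a delete-one jackknife
standard error, and averaged across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .core import SpikeStateError, SpikeTrain, condition_key

__all__ = [
    "CorrelationPair",
    "binned_counts",
    "ccg_shift_corrected",
    "r_ccg",
    "fit_timescale",
    "spike_count_correlation",
]

CCG_BIN = 0.001  # s
COUNT_WINDOW = (0.5, 1.5)  # s after stimulus onset


def binned_counts(
    train: SpikeTrain, onsets: np.ndarray, duration: float, bin_width: float = CCG_BIN
) -> np.ndarray:
    """(n_trials, n_bins) spike counts aligned to the trial onsets."""
    n_bins = int(round(duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    out = np.empty((len(onsets), n_bins))
    for i, on in enumerate(onsets):
        t = train.in_window(on, on + n_bins * bin_width) - on
        out[i] = np.histogram(t, bins=edges)[0]
    return out


@dataclass
class CorrelationPair:
    """Corrected correlograms of one unit pair for one trial ensemble."""

    unit_i: str
    unit_j: str
    lags: np.ndarray  # s, symmetric around 0
    ccg: np.ndarray  # corrected cross-correlogram (count product units)
    acg_1: np.ndarray
    acg_2: np.ndarray
    bin_width: float
    n_trials: int
    trial_duration: float
    predictor: str

    def zero_lag_index(self) -> int:
        return self.lags.size // 2


def _xcorr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sum over rows of the full cross-correlation Sum_t a_k(t) b_k(t+tau)."""
    # correlate(b_k, a_k, 'full')[tau + n - 1] = Sum_t a_k(t) b_k(t + tau)
    n = a.shape[1]
    out = np.zeros(2 * n - 1)
    for ak, bk in zip(a, b):
        out += signal.fftconvolve(bk, ak[::-1], mode="full")
    return out


def ccg_shift_corrected(
    train_i: SpikeTrain,
    train_j: SpikeTrain,
    trials: pd.DataFrame,
    *,
    bin_width: float = CCG_BIN,
    predictor: str = "shuffle",
) -> CorrelationPair:
    """Stimulus-corrected CCG and ACGs over same-condition trials.

    ``trials`` must hold at least two trials of a single condition. See the
    module docstring for the two predictor variants.
    """
    if len(trials) < 2:
        raise SpikeStateError("shift predictor undefined with a single trial")
    if predictor not in ("shuffle", "shift"):
        raise SpikeStateError("predictor must be 'shuffle' or 'shift'")
    dur = float(trials["duration"].min())
    onsets = trials["onset"].to_numpy(dtype=float)
    x = binned_counts(train_i, onsets, dur, bin_width)
    y = binned_counts(train_j, onsets, dur, bin_width)
    m, n = x.shape

    raw_ccg = _xcorr_rows(x, y) / m
    raw_a1 = _xcorr_rows(x, x) / m
    raw_a2 = _xcorr_rows(y, y) / m

    if predictor == "shuffle":
        sx, sy = x.sum(axis=0), y.sum(axis=0)
        pred = signal.fftconvolve(sy, sx[::-1], mode="full") / m**2
        ccg = raw_ccg - pred
        acg1 = raw_a1 - signal.fftconvolve(sx, sx[::-1], mode="full") / m**2
        acg2 = raw_a2 - signal.fftconvolve(sy, sy[::-1], mode="full") / m**2
    else:  # one-trial shift: pair trial k of unit i with trial k+1 of unit j
        pred = _xcorr_rows(x, np.roll(y, -1, axis=0)) / m
        ccg = raw_ccg - pred
        acg1, acg2 = raw_a1, raw_a2

    lags = (np.arange(2 * n - 1) - (n - 1)) * bin_width
    return CorrelationPair(
        unit_i=train_i.unit_id,
        unit_j=train_j.unit_id,
        lags=lags,
        ccg=ccg,
        acg_1=acg1,
        acg_2=acg2,
        bin_width=bin_width,
        n_trials=m,
        trial_duration=n * bin_width,
        predictor=predictor,
    )


def r_ccg(pair: CorrelationPair, t_grid: np.ndarray) -> np.ndarray:
    """Windowed normalized correlogram integral at each half-width in ``t_grid``.

    Entries with a non-positive denominator are NaN.
    """
    center = pair.zero_lag_index()
    n = center + 1
    # cumulative symmetric-window sums: window W covers lags -W..W
    def sym_cumsum(arr: np.ndarray) -> np.ndarray:
        out = np.empty(n)
        out[0] = arr[center]
        left = arr[center - 1 :: -1]
        right = arr[center + 1 :]
        out[1:] = out[0] + np.cumsum(left + right)
        return out

    c = sym_cumsum(pair.ccg)
    a1 = sym_cumsum(pair.acg_1)
    a2 = sym_cumsum(pair.acg_2)
    out = np.empty(len(t_grid))
    for i, t in enumerate(np.asarray(t_grid, dtype=float)):
        w = min(int(round(t / pair.bin_width)), n - 1)
        den = a1[w] * a2[w]
        out[i] = c[w] / np.sqrt(den) if den > 0 else np.nan
    return out


def fit_timescale(
    t_grid: np.ndarray, r_series: np.ndarray
) -> tuple[float, dict]:
    """Fit ``A * (1 - exp(-t / tau))`` to a saturating r_CCG series.

    Returns ``(tau, info)`` where ``info`` holds the amplitude, the variance
    explained and a ``reliable`` flag (False for non-saturating series or a
    tau at the search bound).
    """
    t = np.asarray(t_grid, dtype=float)
    r = np.asarray(r_series, dtype=float)
    ok = np.isfinite(r)
    t, r = t[ok], r[ok]
    if t.size < 5:
        raise SpikeStateError("timescale fit needs >= 5 points")
    rmax = float(np.max(np.abs(r)))
    saturating = rmax > 0 and abs(r[-1]) >= 0.8 * rmax
    tau_lo = 1e-6
    a0 = r[-1] if r[-1] != 0 else rmax
    # tau seed: first crossing of 63% of the plateau
    above = np.flatnonzero(np.abs(r) >= 0.632 * abs(a0)) if a0 else []
    tau0 = float(t[above[0]]) if len(above) else float(t[t.size // 2])
    tau0 = max(tau0, 10 * tau_lo)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, A, tau: A * (1.0 - np.exp(-tt / tau)),
            t, r, p0=[a0, tau0],
            bounds=([-np.inf, tau_lo], [np.inf, np.inf]),
            maxfev=10000,
        )
        A, tau = float(popt[0]), float(popt[1])
        fitted = A * (1.0 - np.exp(-t / tau))
        sst = float(np.sum((r - r.mean()) ** 2))
        r2 = 1.0 - float(np.sum((r - fitted) ** 2)) / sst if sst > 0 else 1.0
    except RuntimeError:
        return float("nan"), {"amplitude": float("nan"), "r2": 0.0, "reliable": False}
    # a timescale finer than the first grid point is not resolved (a flat
    # series drives tau toward the zero bound)
    reliable = saturating and tau > 2 * tau_lo and tau >= t[0]
    return tau, {"amplitude": A, "r2": r2, "reliable": reliable}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _jackknife_se(x: np.ndarray, y: np.ndarray, max_deletions: int = 100) -> float:
    """Delete-one-trial jackknife SE of the Pearson correlation."""
    n = x.size
    m = min(n, max_deletions)
    thetas = np.empty(m)
    for i in range(m):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        thetas[i] = _pearson(x[mask], y[mask])
    return float(np.sqrt((m - 1) / m * np.sum((thetas - thetas.mean()) ** 2)))


def spike_count_correlation(
    train_i: SpikeTrain,
    train_j: SpikeTrain,
    trials: pd.DataFrame,
    *,
    window: tuple[float, float] = COUNT_WINDOW,
    min_trials: int = 10,
    max_jackknife: int = 100,
) -> dict:
    """Condition-averaged spike-count correlation of one pair.

    Counts are taken in ``[onset + window[0], onset + window[1])``; each
    condition with >= ``min_trials`` trials and non-zero count variance in
    both units contributes a Pearson correlation and a jackknife SE; results
    are averaged across conditions. Conditions with zero variance are
    excluded and counted.
    """
    w0, w1 = window
    if not w1 > w0:
        raise SpikeStateError("empty count window")
    per_cond = []
    n_excluded = 0
    for cond, grp in trials.groupby(condition_key(trials)):
        if len(grp) < min_trials:
            continue
        on = grp["onset"].to_numpy(dtype=float)
        x = np.array([train_i.in_window(o + w0, o + w1).size for o in on], dtype=float)
        y = np.array([train_j.in_window(o + w0, o + w1).size for o in on], dtype=float)
        if x.std() == 0 or y.std() == 0:
            n_excluded += 1
            continue
        per_cond.append(
            {
                "condition": cond,
                "r": _pearson(x, y),
                "se": _jackknife_se(x, y, max_jackknife),
                "n_trials": len(grp),
            }
        )
    if not per_cond:
        return {"r_sc": float("nan"), "se": float("nan"), "n_conditions": 0,
                "n_excluded": n_excluded, "per_condition": []}
    rs = np.array([c["r"] for c in per_cond])
    ses = np.array([c["se"] for c in per_cond])
    return {
        "r_sc": float(rs.mean()),
        # SE of the condition-averaged correlation, conditions independent
        "se": float(np.sqrt(np.sum(ses**2)) / ses.size),
        "n_conditions": len(per_cond),
        "n_excluded": n_excluded,
        "per_condition": per_cond,
    }
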