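"""Trial classification by locomotion state and behavioral summaries.

A trial counts as *locomotion* when the treadmill speed exceeds 1 cm/s for at
least 80% of the trial duration, *stationary* when it stays below 0.25 cm/s
for at least 80%, and *unclassified* otherwise. Occupancy is a time-weighted
integral of the threshold indicator (piecewise-constant interpolation of the
speed trace), so irregular sampling cannot bias the classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AbsentChannelError, BehaviorTrace, CoverageError, SpikeStateError, condition_key

__all__ = ["BoutSummary", "classify_trials", "bout_statistics", "state_triggered_average"]

LOCO_THRESH = 1.0  # cm/s
STAT_THRESH = 0.25  # cm/s
OCCUPANCY = 0.80


@dataclass
class BoutSummary:
    """Contiguous behavioral bouts and their duration statistics."""

    bouts: pd.DataFrame  # columns start, stop, state
    median_duration: dict[str, float]
    mean_duration: dict[str, float]
    trial_fractions: pd.DataFrame | None = None  # per condition x state


def _occupancy_fractions(
    trace: BehaviorTrace, onset: float, stop: float, loco_thresh: float, stat_thresh: float
) -> tuple[float, float]:
    """Time-weighted fraction of [onset, stop) above/below the thresholds."""
    t = trace.timestamps
    if onset < t[0] - 1e-9 or stop > t[-1] + 1e-9:
        raise CoverageError(
            f"trial [{onset}, {stop}) outside behavior trace span {trace.span}"
        )
    # sample boundaries clipped to the window; each speed sample is held
    # constant until the next timestamp (piecewise-constant interpolation)
    i0 = max(int(np.searchsorted(t, onset, side="right")) - 1, 0)
    i1 = int(np.searchsorted(t, stop, side="left"))
    seg_t = np.clip(t[i0 : i1 + 1], onset, stop)
    if seg_t[-1] < stop:  # window extends past the last sample
        seg_t = np.append(seg_t, stop)
    widths = np.diff(seg_t)
    v = trace.speed[i0 : i0 + widths.size]
    total = stop - onset
    above = float(widths[v > loco_thresh].sum()) / total
    below = float(widths[v < stat_thresh].sum()) / total
    return above, below


def classify_trials(
    trace: BehaviorTrace,
    trials: pd.DataFrame,
    loco_thresh: float = LOCO_THRESH,
    stat_thresh: float = STAT_THRESH,
    occupancy: float = OCCUPANCY,
) -> pd.DataFrame:
    """Return a copy of the trial table with the ``state`` column assigned.

    Every trial receives exactly one of ``locomotion``, ``stationary`` or
    ``unclassified`` (the thresholds cannot both be satisfied when
    ``occupancy > 0.5``).
    """
    if not 0 < occupancy <= 1:
        raise SpikeStateError("occupancy must be in (0, 1]")
    out = trials.copy()
    states = []
    for onset, dur in zip(out["onset"], out["duration"]):
        above, below = _occupancy_fractions(trace, onset, onset + dur, loco_thresh, stat_thresh)
        if above >= occupancy:
            states.append("locomotion")
        elif below >= occupancy:
            states.append("stationary")
        else:
            states.append("unclassified")
    out["state"] = states
    return out


def bout_statistics(
    trace: BehaviorTrace,
    loco_thresh: float = LOCO_THRESH,
    stat_thresh: float = STAT_THRESH,
    min_bout: float = 0.5,
    trials: pd.DataFrame | None = None,
) -> BoutSummary:
    """Segment the session into locomotion/stationary bouts.

    Samples with speed between the two thresholds are attached to the
    preceding bout; bouts shorter than ``min_bout`` are merged into their
    neighbors (classification of individual trials never uses this merging).
    When a labeled trial table is given, per-condition state fractions are
    included.
    """
    t = trace.timestamps
    v = trace.speed
    lab = np.where(v > loco_thresh, 1, np.where(v < stat_thresh, 0, -1))
    # indeterminate samples inherit the previous determinate label
    if np.any(lab != -1):
        lab[0] = lab[np.argmax(lab != -1)] if lab[0] == -1 else lab[0]
        known = np.where(lab != -1, np.arange(lab.size), 0)
        np.maximum.accumulate(known, out=known)
        lab = lab[known]
    else:
        lab = np.zeros_like(lab)

    # run-length encode
    change = np.flatnonzero(np.diff(lab)) + 1
    starts_idx = np.concatenate(([0], change))
    seg_start = t[starts_idx]
    seg_stop = np.append(t[starts_idx[1:]], t[-1])
    seg_lab = lab[starts_idx]

    # absorb bouts shorter than min_bout into their predecessor (single
    # left-to-right pass), then coalesce adjacent same-label bouts
    segs = list(zip(seg_start.tolist(), seg_stop.tolist(), seg_lab.tolist()))
    absorbed: list[tuple[float, float, int]] = []
    for s0, s1, sl in segs:
        if absorbed and s1 - s0 < min_bout:
            p0, p1, pl = absorbed[-1]
            absorbed[-1] = (p0, s1, pl)
        elif absorbed and absorbed[-1][1] - absorbed[-1][0] < min_bout:
            # leading fragment: give it the label of the first full bout
            p0, _, _ = absorbed[-1]
            absorbed[-1] = (p0, s1, sl)
        else:
            absorbed.append((s0, s1, sl))
    out: list[tuple[float, float, int]] = []
    for s0, s1, sl in absorbed:
        if out and out[-1][2] == sl:
            out[-1] = (out[-1][0], s1, sl)
        else:
            out.append((s0, s1, sl))

    bouts = pd.DataFrame(
        {
            "start": [s for s, _, _ in out],
            "stop": [e for _, e, _ in out],
            "state": ["locomotion" if l == 1 else "stationary" for _, _, l in out],
        }
    )
    durs = bouts["stop"] - bouts["start"]
    median = {
        st: float(durs[bouts["state"] == st].median()) if (bouts["state"] == st).any() else float("nan")
        for st in ("locomotion", "stationary")
    }
    mean = {
        st: float(durs[bouts["state"] == st].mean()) if (bouts["state"] == st).any() else float("nan")
        for st in ("locomotion", "stationary")
    }

    fractions = None
    if trials is not None and "state" in trials.columns:
        key = condition_key(trials)
        fractions = (
            trials.assign(condition=key)
            .groupby("condition")["state"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
    return BoutSummary(bouts, median, mean, fractions)


def state_triggered_average(
    trace: BehaviorTrace,
    events: dict[str, np.ndarray],
    window: tuple[float, float] = (-2.0, 4.0),
) -> dict[str, dict[str, np.ndarray]]:
    """Event-aligned pupil average per state.

    ``events`` maps a state label to event (e.g. trial or bout onset) times;
    each state needs at least two events. NaN pupil samples (blinks, bad
    fits) are excluded pairwise. Returns per state the lag grid, mean and
    standard error.
    """
    if trace.pupil is None:
        raise AbsentChannelError("behavior trace has no pupil channel")
    dt = float(np.median(np.diff(trace.timestamps)))
    lags = np.arange(window[0], window[1] + dt / 2, dt)
    out: dict[str, dict[str, np.ndarray]] = {}
    for state, ev in events.items():
        ev = np.asarray(ev, dtype=float)
        if ev.size < 2:
            raise SpikeStateError(f"state {state!r} has fewer than 2 events")
        rows = np.empty((ev.size, lags.size))
        for i, e in enumerate(ev):
            rows[i] = np.interp(
                e + lags, trace.timestamps, trace.pupil, left=np.nan, right=np.nan
            )
        n = np.sum(np.isfinite(rows), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(rows, axis=0)
            sd = np.nanstd(rows, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        out[state] = {"lags": lags, "mean": mean, "sem": sem, "n": n}
    return out
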