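"""Core data containers shared by every analysis stage.

The package works on three kinds of objects:

* :class:`SpikeTrain` -- one unit's sorted event times over a recording.
* a *trial table* -- a :class:`pandas.DataFrame` with one row per stimulus
  epoch (columns ``trial_id, onset, duration, stimulus_class, parameter,
  state``); intervals are half-open ``[onset, onset + duration)``.
* :class:`BehaviorTrace` -- a timestamped treadmill-speed series with an
  optional pupil-diameter channel.

Trial tables are plain DataFrames rather than a bespoke class so that the
usual pandas idioms (filtering by condition, groupby summaries, TSV round
trips) stay available to users.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised stimulus classes in a trial table
STIM_CLASSES = ("tf_grating", "sf_grating", "contrast_reversal", "blank")

#: behavioral state labels assigned by :func:`spikestate.behavior.classify_trials`
STATES = ("locomotion", "stationary", "unclassified")

TRIAL_COLUMNS = ["trial_id", "onset", "duration", "stimulus_class", "parameter", "state"]

#: spike times closer than this are considered duplicates (seconds)
DEDUP_RESOLUTION = 1e-4


class SpikeStateError(ValueError):
    """Base class for validation errors raised by this package."""


class CoverageError(SpikeStateError):
    """A trial lies (partly) outside the span of the behavior trace."""


class DegenerateSessionError(SpikeStateError):
    """The requested session is too short to contain a single behavioral bout."""


class AbsentChannelError(SpikeStateError):
    """An optional data channel (e.g. pupil diameter) is required but missing."""


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit over a recording session.

    Parameters
    ----------
    unit_id:
        Unit label, unique within a session.
    spike_times:
        Event times in seconds, sorted ascending; duplicates closer than
        0.1 ms are removed on construction.
    span:
        Session duration in seconds; all spikes must fall in ``[0, span]``.
    region:
        Anatomical tag, one of ``{"dLGN", "V1", "unknown"}``.
    """

    unit_id: str
    spike_times: np.ndarray
    span: float
    region: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        t = np.sort(t)
        if t.size:
            keep = np.concatenate(([True], np.diff(t) >= DEDUP_RESOLUTION))
            t = t[keep]
            if t[0] < 0 or t[-1] > self.span:
                raise SpikeStateError(
                    f"unit {self.unit_id}: spikes outside session span [0, {self.span}]"
                )
        self.spike_times = t
        if self.region not in ("dLGN", "V1", "unknown"):
            raise SpikeStateError(f"unknown region tag {self.region!r}")

    def __len__(self) -> int:
        return self.spike_times.size

    def in_window(self, start: float, stop: float) -> np.ndarray:
        """Spike times in the half-open window ``[start, stop)``."""
        i = np.searchsorted(self.spike_times, [start, stop], side="left")
        return self.spike_times[i[0] : i[1]]

    def rate(self) -> float:
        """Mean firing rate over the whole session (spikes/s)."""
        return len(self) / self.span if self.span > 0 else 0.0


@dataclass
class BehaviorTrace:
    """Treadmill speed (and optionally pupil diameter) over a session.

    ``timestamps`` must be strictly increasing; ``speed`` is non-negative in
    cm/s. ``pupil`` is in mm and may contain NaN gaps (blinks, bad ellipse
    fits); gaps are excluded from averages downstream.
    """

    timestamps: np.ndarray
    speed: np.ndarray
    pupil: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise SpikeStateError("behavior trace needs >= 2 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise SpikeStateError("behavior timestamps must be strictly increasing")
        if self.speed.shape != self.timestamps.shape:
            raise SpikeStateError("speed and timestamps shapes differ")
        if np.any(self.speed < 0):
            raise SpikeStateError("speed must be non-negative")
        if self.pupil is not None:
            self.pupil = np.asarray(self.pupil, dtype=float)
            if self.pupil.shape != self.timestamps.shape:
                raise SpikeStateError("pupil and timestamps shapes differ")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])


def make_trial_table(
    onsets: np.ndarray,
    durations: np.ndarray,
    stimulus_class: np.ndarray,
    parameter: np.ndarray,
    state: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble and validate a trial table."""
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    n = onsets.size
    df = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "onset": onsets,
            "duration": durations,
            "stimulus_class": np.asarray(stimulus_class, dtype=object),
            "parameter": np.asarray(parameter, dtype=float),
            "state": np.full(n, "unclassified", dtype=object) if state is None else state,
        }
    )
    validate_trials(df)
    return df


def validate_trials(trials: pd.DataFrame) -> None:
    """Check schema, positivity and non-overlap of a trial table."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns and c != "state"]
    if missing:
        raise SpikeStateError(f"trial table missing columns {missing}")
    if np.any(trials["duration"].to_numpy() <= 0):
        raise SpikeStateError("trial durations must be positive")
    bad = ~trials["stimulus_class"].isin(STIM_CLASSES)
    if bad.any():
        raise SpikeStateError(
            f"unknown stimulus classes {sorted(trials.loc[bad, 'stimulus_class'].unique())}"
        )
    order = trials.sort_values("onset")
    ends = (order["onset"] + order["duration"]).to_numpy()
    starts = order["onset"].to_numpy()
    overlap = starts[1:] < ends[:-1] - 1e-12
    if overlap.any():
        ids = order["trial_id"].to_numpy()
        first = int(np.argmax(overlap))
        raise SpikeStateError(
            f"overlapping trials {ids[first]} and {ids[first + 1]}"
        )


def condition_key(trials: pd.DataFrame) -> pd.Series:
    """Condition label per trial: stimulus class plus parameter where present."""
    param = trials["parameter"]
    lab = trials["stimulus_class"].astype(str)
    has_param = param.notna()
    return lab.where(~has_param, lab + "@" + param.map(lambda v: f"{v:g}"))
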