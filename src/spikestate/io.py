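"""Interchange TSV formats (tab-delimited, header row, UTF-8).

* ``spikes.tsv``   -- ``unit_id, time_s`` (one row per spike), optional ``region``
* ``trials.tsv``   -- ``trial_id, onset_s, duration_s, stimulus_class, parameter, state``
* ``behavior.tsv`` -- ``time_s, speed_cmps`` and optionally ``pupil_mm``

Times are seconds on a 0-based session clock, written with six fractional
digits; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BehaviorTrace, SpikeStateError, SpikeTrain, validate_trials
from .synth import SynthGroundTruth

FLOAT_FMT = "%.6f"


def write_spikes(path: str | Path, trains: list[SpikeTrain]) -> None:
    rows = []
    for tr in trains:
        rows.append(
            pd.DataFrame(
                {"unit_id": tr.unit_id, "time_s": tr.spike_times, "region": tr.region}
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["unit_id", "time_s", "region"]
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_spikes(path: str | Path, span: float) -> list[SpikeTrain]:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise SpikeStateError(f"{path}: no spikes")
    if not {"unit_id", "time_s"}.issubset(df.columns):
        raise SpikeStateError(f"{path}: needs columns unit_id, time_s")
    trains = []
    for uid, sub in df.groupby("unit_id", sort=True):
        region = str(sub["region"].iloc[0]) if "region" in sub.columns else "unknown"
        trains.append(SpikeTrain(str(uid), sub["time_s"].to_numpy(), span, region))
    return trains


def write_trials(path: str | Path, trials: pd.DataFrame) -> None:
    out = trials.rename(columns={"onset": "onset_s", "duration": "duration_s"})
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"onset_s": "onset", "duration_s": "duration"})
    if "state" not in df.columns:
        df["state"] = "unclassified"
    validate_trials(df)
    return df


def write_behavior(path: str | Path, trace: BehaviorTrace) -> None:
    data = {"time_s": trace.timestamps, "speed_cmps": trace.speed}
    if trace.pupil is not None:
        data["pupil_mm"] = trace.pupil
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_behavior(path: str | Path) -> BehaviorTrace:
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "speed_cmps"}.issubset(df.columns):
        raise SpikeStateError(f"{path}: needs columns time_s, speed_cmps")
    pupil = df["pupil_mm"].to_numpy() if "pupil_mm" in df.columns else None
    return BehaviorTrace(df["time_s"].to_numpy(), df["speed_cmps"].to_numpy(), pupil)


def write_ground_truth(path: str | Path, gt: SynthGroundTruth) -> None:
    payload = {
        "units": [
            {
                "unit_id": u.unit_id,
                "baseline_rate": u.baseline_rate,
                "tuning": list(u.tuning),
                "response_phase": u.response_phase,
                "loco_gain": u.loco_gain,
                "cell_class": u.cell_class,
                "f2_weight": u.f2_weight,
                "shared_noise_weight": u.shared_noise_weight,
                "gain_noise_cv": u.gain_noise_cv,
                "region": u.region,
            }
            for u in gt.units
        ],
        "bouts": gt.bouts.to_dict(orient="list"),
        "shared_draws": gt.shared_draws.tolist(),
        "trial_gains": {k: v.tolist() for k, v in gt.trial_gains.items()},
    }
    Path(path).write_text(json.dumps(payload))


def validate_inputs(
    spikes_path: str | Path, trials_path: str | Path, behavior_path: str | Path
) -> dict:
    """Schema and consistency checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings: list[str] = []

    try:
        trace = read_behavior(behavior_path)
    except Exception as e:  # noqa: BLE001 - surfaced in the report
        errors.append(f"behavior: {e}")
        trace = None

    trials = None
    try:
        trials = read_trials(trials_path)
    except Exception as e:
        errors.append(f"trials: {e}")

    if trace is not None and trials is not None:
        t0, t1 = trace.span
        outside = trials[(trials["onset"] < t0) | (trials["onset"] + trials["duration"] > t1 + 1e-6)]
        for tid in outside["trial_id"]:
            errors.append(f"trials: trial {tid} outside behavior trace span")

    try:
        span = trace.span[1] if trace is not None else np.inf
        df = pd.read_csv(spikes_path, sep="\t")
        if df.empty or "time_s" not in df.columns:
            errors.append("spikes: empty or missing time_s column")
        else:
            if df["time_s"].min() < 0:
                errors.append("spikes: negative spike time")
            if np.isfinite(span) and df["time_s"].max() > span + 1e-6:
                errors.append("spikes: spike time beyond session span")
            per_unit = df.groupby("unit_id")["time_s"].apply(
                lambda s: bool(np.all(np.diff(s.to_numpy()) >= 0))
            )
            for uid, sorted_ok in per_unit.items():
                if not sorted_ok:
                    warnings.append(f"spikes: unit {uid} not sorted (will be sorted on load)")
    except FileNotFoundError as e:
        errors.append(f"spikes: {e}")

    return {"errors": errors, "warnings": warnings}
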