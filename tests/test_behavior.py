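"""Trial classification, bout segmentation and pupil averaging."""

import numpy as np
import pytest

import spikestate as ss
from spikestate.core import AbsentChannelError, BehaviorTrace, CoverageError, SpikeStateError
from .conftest import regular_trials


def _const_trace(speed: float, T: float = 10.0, fs: float = 20.0, pupil=None):
    t = np.arange(0.0, T, 1.0 / fs)
    p = None if pupil is None else np.full(t.size, pupil)
    return BehaviorTrace(t, np.full(t.size, speed), p)


@pytest.mark.parametrize(
    "speed,expected",
    [(5.0, "locomotion"), (0.0, "stationary"), (0.5, "unclassified")],
)
def test_classify_constant_speed(speed, expected):
    trace = _const_trace(speed)
    trials = regular_trials(2, duration=2.0, gap=1.0)
    out = ss.classify_trials(trace, trials)
    assert (out["state"] == expected).all()


def test_classify_mixed_trial_is_unclassified():
    # 1.5 s at 2 cm/s then 0.5 s at 0: 75% occupancy for both criteria
    t = np.arange(0.0, 2.0, 0.05)
    v = np.where(t < 1.5, 2.0, 0.0)
    trace = BehaviorTrace(t, v)
    trials = regular_trials(1, duration=1.95, gap=0.0)
    out = ss.classify_trials(trace, trials)
    assert out["state"].iloc[0] == "unclassified"


def test_classify_partition_and_resampling_stability():
    cfg = ss.SynthConfig(rng_seed=3, session_length=600.0, sample_rate=20.0,
                         unit_specs=(ss.UnitSpec("u"),))
    trace20, _ = ss.generate_behavior(cfg, with_pupil=False)
    trials = ss.generate_trials(cfg, "tf")
    lab20 = ss.classify_trials(trace20, trials)
    assert set(lab20["state"]) <= {"locomotion", "stationary", "unclassified"}
    assert lab20["state"].notna().all()
    # piecewise-constant resampling at 3x the rate: labels essentially stable
    t3 = np.arange(0.0, 600.0, 1.0 / 60.0)
    idx = np.searchsorted(trace20.timestamps, t3, side="right") - 1
    trace60 = BehaviorTrace(t3, trace20.speed[np.clip(idx, 0, None)])
    lab60 = ss.classify_trials(trace60, trials)
    flips = (lab20["state"] != lab60["state"]).mean()
    assert flips <= 0.01


def test_classify_monotone_in_threshold():
    cfg = ss.SynthConfig(rng_seed=4, session_length=300.0, unit_specs=(ss.UnitSpec("u"),))
    trace, _ = ss.generate_behavior(cfg, with_pupil=False)
    trials = ss.generate_trials(cfg, "tf")
    lo = ss.classify_trials(trace, trials, loco_thresh=1.0)
    hi = ss.classify_trials(trace, trials, loco_thresh=3.0)
    became_loco = (lo["state"] != "locomotion") & (hi["state"] == "locomotion")
    assert not became_loco.any()


def test_classify_coverage_error():
    trace = _const_trace(5.0, T=3.0)
    trials = regular_trials(2, duration=2.0, gap=1.0)  # second trial ends at 5 s
    with pytest.raises(CoverageError):
        ss.classify_trials(trace, trials)


def test_bouts_all_zero_speed_single_stationary():
    trace = _const_trace(0.0, T=20.0)
    summary = ss.bout_statistics(trace)
    assert len(summary.bouts) == 1
    assert summary.bouts["state"].iloc[0] == "stationary"


def test_bouts_square_wave_alternation():
    t = np.arange(0.0, 60.0, 0.05)
    v = np.where((t // 10) % 2 == 0, 10.0, 0.0)
    summary = ss.bout_statistics(BehaviorTrace(t, v))
    durs = (summary.bouts["stop"] - summary.bouts["start"]).to_numpy()
    assert np.allclose(durs[:-1], 10.0, atol=0.1)
    states = list(summary.bouts["state"])
    assert all(a != b for a, b in zip(states, states[1:]))


def test_bout_medians_match_generator():
    cfg = ss.SynthConfig(rng_seed=6, session_length=7200.0, unit_specs=(ss.UnitSpec("u"),))
    trace, bouts = ss.generate_behavior(cfg, with_pupil=False)
    summary = ss.bout_statistics(trace)
    # modest session here; the full 10k-bout calibration lives in acceptance
    assert summary.median_duration["locomotion"] == pytest.approx(6.4, rel=0.25)
    assert summary.median_duration["stationary"] == pytest.approx(8.8, rel=0.25)
    starts = summary.bouts["start"].to_numpy()
    stops = summary.bouts["stop"].to_numpy()
    assert np.allclose(starts[1:], stops[:-1])  # bouts tile the session


def test_pupil_constant_flat_average():
    trace = _const_trace(0.0, T=30.0, pupil=2.0)
    out = ss.state_triggered_average(trace, {"stationary": np.array([10.0, 20.0])},
                                     window=(-1.0, 2.0))
    assert np.allclose(out["stationary"]["mean"], 2.0)
    assert np.allclose(out["stationary"]["sem"], 0.0)


def test_pupil_dilation_locomotion_exceeds_stationary():
    cfg = ss.SynthConfig(rng_seed=8, session_length=1200.0, unit_specs=(ss.UnitSpec("u"),))
    trace, bouts = ss.generate_behavior(cfg, with_pupil=True)
    ev = {
        "locomotion": bouts.loc[bouts["state"] == "locomotion", "start"].to_numpy()[1:],
        "stationary": bouts.loc[bouts["state"] == "stationary", "start"].to_numpy()[1:],
    }
    out = ss.state_triggered_average(trace, ev, window=(0.5, 4.0))
    sel = out["locomotion"]["lags"] > 1.0
    assert np.nanmean(out["locomotion"]["mean"][sel]) > np.nanmean(out["stationary"]["mean"][sel])


def test_pupil_errors():
    with pytest.raises(AbsentChannelError):
        ss.state_triggered_average(_const_trace(0.0), {"stationary": np.array([1.0, 2.0])})
    with pytest.raises(SpikeStateError):
        ss.state_triggered_average(_const_trace(0.0, pupil=2.0), {"stationary": np.array([1.0])})
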