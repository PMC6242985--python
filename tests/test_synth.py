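"""Generator contracts: determinism, schedule arithmetic, rate calibration."""

import numpy as np
import pandas as pd
import pytest

import spikestate as ss
from spikestate.core import DegenerateSessionError, SpikeStateError


def _one_unit_config(**kw):
    spec = ss.UnitSpec("u0", baseline_rate=kw.pop("baseline_rate", 10.0),
                       tuning=kw.pop("tuning", (4.0, 0.0, 1.0, 0.0, 0.0)), **kw)
    return ss.SynthConfig(rng_seed=5, session_length=240.0, unit_specs=(spec,))


def test_seed_determinism_bit_identical():
    cfg = _one_unit_config(loco_gain=1.3, gain_noise_cv=0.2)
    a = ss.simulate_session(cfg, "tf")
    b = ss.simulate_session(cfg, "tf")
    assert np.array_equal(a.trace.speed, b.trace.speed)
    assert a.trials.equals(b.trials)
    assert np.array_equal(a.trains[0].spike_times, b.trains[0].spike_times)
    assert np.array_equal(a.ground_truth.shared_draws, b.ground_truth.shared_draws)


def test_spikes_sorted_within_span():
    sess = ss.simulate_session(_one_unit_config(tuning=(4.0, 5.0, 1.0, 1.0, 1.0)), "tf")
    t = sess.trains[0].spike_times
    assert np.all(np.diff(t) > 0)
    assert t[0] >= 0 and t[-1] <= sess.trains[0].span


def test_tf_block_schedule_arithmetic():
    # one block: 5 TFs + blank, each 2.0 s
    cfg = ss.SynthConfig(rng_seed=0, session_length=18.0,
                         unit_specs=(ss.UnitSpec("u"),))
    trials = ss.generate_trials(cfg, "tf")
    assert len(trials) == 6
    assert np.allclose(trials["duration"], 2.0)
    stim = trials[trials["stimulus_class"] == "tf_grating"]
    assert sorted(stim["parameter"]) == [1, 2, 4, 8, 16]
    assert (trials["stimulus_class"] == "blank").sum() == 1


def test_default_session_repeat_count_30_to_50():
    cfg = ss.SynthConfig(rng_seed=0, unit_specs=(ss.UnitSpec("u"),))
    trials = ss.generate_trials(cfg, "tf")
    counts = trials.groupby("stimulus_class")["trial_id"].count()
    per_cond = trials[trials["stimulus_class"] == "tf_grating"].groupby("parameter").size()
    assert all(30 <= c <= 50 for c in per_cond)
    assert 30 <= counts["blank"] <= 50


def test_contrast_reversal_two_cycles_per_trial():
    cfg = ss.SynthConfig(rng_seed=0, session_length=120.0, unit_specs=(ss.UnitSpec("u"),))
    trials = ss.generate_trials(cfg, "cr")
    rev = trials[trials["stimulus_class"] == "contrast_reversal"]
    assert np.allclose(rev["duration"] * rev["parameter"], 2.0)  # 2 s at 1 Hz


def test_degenerate_session_raises():
    cfg = ss.SynthConfig(rng_seed=0, session_length=0.05, unit_specs=(ss.UnitSpec("u"),))
    with pytest.raises(DegenerateSessionError):
        ss.generate_behavior(cfg)


def test_sigma_zero_strictly_alternating_equal_bouts():
    cfg = ss.SynthConfig(rng_seed=1, session_length=50.0, loco_bout_median=5.0,
                         stat_bout_median=5.0, bout_lognorm_sigma=0.0,
                         unit_specs=(ss.UnitSpec("u"),))
    _, bouts = ss.generate_behavior(cfg)
    durs = (bouts["stop"] - bouts["start"]).to_numpy()
    assert np.allclose(durs, 5.0)
    assert all(a != b for a, b in zip(bouts["state"], bouts["state"][1:]))


def test_homogeneous_unit_count_matches_rate():
    # baseline 10 spikes/s, no stimulus terms, no gains: ~N(rate*T, rate*T)
    cfg = _one_unit_config()
    sess = ss.simulate_session(cfg, "tf")
    n = len(sess.trains[0])
    expect = 10.0 * cfg.session_length
    assert abs(n - expect) < 4 * np.sqrt(expect)


def test_loco_gain_rate_ratio_on_baseline():
    cfg = ss.SynthConfig(rng_seed=9, session_length=2400.0,
                         unit_specs=(ss.UnitSpec("u", baseline_rate=12.0,
                                                 tuning=(4.0, 0.0, 1.0, 0.0, 0.0),
                                                 loco_gain=1.3),))
    trace, bouts = ss.generate_behavior(cfg, with_pupil=False)
    trials = ss.generate_trials(cfg, "tf")
    trains, _ = ss.generate_spikes(cfg, trials, bouts)
    t = trains[0].spike_times
    rates = {}
    for state in ("locomotion", "stationary"):
        sel = bouts[bouts["state"] == state]
        dur = float((sel["stop"] - sel["start"]).sum())
        n = sum(trains[0].in_window(a, b).size for a, b in zip(sel["start"], sel["stop"]))
        rates[state] = n / dur
    assert rates["locomotion"] / rates["stationary"] == pytest.approx(1.3, rel=0.05)


def test_speed_moments_inside_locomotion_bouts():
    cfg = ss.SynthConfig(rng_seed=2, session_length=3600.0, unit_specs=(ss.UnitSpec("u"),))
    trace, bouts = ss.generate_behavior(cfg, with_pupil=False)
    # bouts tile [0, T]; assign each sample to the bout containing it
    idx = np.searchsorted(bouts["start"].to_numpy(), trace.timestamps, "right") - 1
    loco = bouts["state"].to_numpy()[idx] == "locomotion"
    assert trace.speed[loco].mean() == pytest.approx(13.6, rel=0.05)
    assert np.all(trace.speed[~loco] < 0.25)


def test_shared_noise_pair_positive_count_correlation():
    # analytic oracle for the lognormal shared-gain model:
    # r = L1*L2*v / sqrt((L1 + L1^2 v)(L2 + L2^2 v)), v = exp(w^2) - 1
    w, b1, b2 = 0.3, 15.0, 12.0
    specs = (ss.UnitSpec("a", baseline_rate=b1, tuning=(4, 0, 1, 0, 0), shared_noise_weight=w),
             ss.UnitSpec("b", baseline_rate=b2, tuning=(4, 0, 1, 0, 0), shared_noise_weight=w))
    cfg = ss.SynthConfig(rng_seed=11, session_length=720.0, unit_specs=specs)
    trials = ss.generate_trials(cfg, "tf")
    bouts = pd.DataFrame({"start": [0.0], "stop": [720.0], "state": ["stationary"]})
    trains, _ = ss.generate_spikes(cfg, trials, bouts)
    res = ss.spike_count_correlation(trains[0], trains[1],
                                     trials.assign(state="stationary"))
    v = np.exp(w * w) - 1.0
    L1, L2 = b1 * 1.0, b2 * 1.0  # counts in the 1-s window
    target = L1 * L2 * v / np.sqrt((L1 + L1**2 * v) * (L2 + L2**2 * v))
    assert res["r_sc"] > 0
    assert res["r_sc"] == pytest.approx(target, abs=0.12)


def test_invalid_configs_rejected():
    with pytest.raises(SpikeStateError):
        ss.SynthConfig(session_length=-1.0)
    with pytest.raises(SpikeStateError):
        ss.SynthConfig(tf_set=(4.0, 2.0, 1.0))
    with pytest.raises(SpikeStateError):
        ss.UnitSpec("u", loco_gain=0.0)
    with pytest.raises(SpikeStateError):
        ss.UnitSpec("u", cell_class="nope")
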