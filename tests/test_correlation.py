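"""Corrected correlograms, r_CCG convergence, timescales, r_SC."""

import numpy as np
import pytest

import spikestate as ss
from spikestate.core import SpikeStateError, SpikeTrain
from spikestate.correlation import binned_counts, fit_timescale
from .conftest import poisson_train, regular_trials


def _pair(rng, n_trials=20, rate=15.0):
    trials = regular_trials(n_trials, parameter=4.0)
    T = trials["onset"].iloc[-1] + 3.0
    a = poisson_train(rng, rate, T, rate + 1, "a")
    b = poisson_train(rng, rate, T, rate + 1, "b")
    return a, b, trials


def test_endpoint_identity_equals_pearson_counts(rng):
    # Eq.-style identity: r_CCG at the full trial window is the Pearson
    # correlation of whole-trial counts, to numerical precision
    for _ in range(5):
        a, b, trials = _pair(rng)
        pair = ss.ccg_shift_corrected(a, b, trials)
        r = ss.r_ccg(pair, np.array([2.0]))[0]
        xa = binned_counts(a, trials["onset"].to_numpy(), 2.0).sum(axis=1)
        xb = binned_counts(b, trials["onset"].to_numpy(), 2.0).sum(axis=1)
        assert abs(r - np.corrcoef(xa, xb)[0, 1]) < 1e-10


def test_independent_pair_rccg_near_zero(rng):
    a, b, trials = _pair(rng, n_trials=40)
    pair = ss.ccg_shift_corrected(a, b, trials)
    grid = np.array([0.05, 0.2, 0.5, 1.0, 2.0])
    r = ss.r_ccg(pair, grid)
    assert np.all(np.abs(r) < 0.25)
    res = ss.spike_count_correlation(a, b, trials.assign(state="all"),
                                     window=(0.0, 2.0))
    assert abs(res["r_sc"]) < 3 * res["se"] + 0.05


def test_duplicated_train_zero_lag_peak(rng):
    trials = regular_trials(10, parameter=4.0)
    T = trials["onset"].iloc[-1] + 3.0
    a = poisson_train(rng, 30.0, T, 31.0, "a")
    dup = SpikeTrain("b", a.spike_times.copy(), T)
    pair = ss.ccg_shift_corrected(a, dup, trials)
    assert int(np.argmax(pair.ccg)) == pair.zero_lag_index()


def test_stimulus_locked_independent_pair_corrected_away(rng):
    # same strong rate profile, independent draws: the corrected CCG should
    # remove the stimulus-locked ("signal") correlation
    trials = regular_trials(40, parameter=4.0)
    T = trials["onset"].iloc[-1] + 3.0
    rate = lambda t: 20.0 + 15.0 * np.cos(2 * np.pi * 4.0 * t)
    a = poisson_train(rng, rate, T, 36.0, "a")
    b = poisson_train(rng, rate, T, 36.0, "b")
    pair = ss.ccg_shift_corrected(a, b, trials)
    raw_scale = np.abs(pair.acg_1).max()
    assert np.abs(pair.ccg).mean() < 0.02 * raw_scale
    r_end = ss.r_ccg(pair, np.array([2.0]))[0]
    assert abs(r_end) < 0.3


def test_shift_predictor_variant_close_to_shuffle(rng):
    a, b, trials = _pair(rng, n_trials=30)
    shuffle = ss.ccg_shift_corrected(a, b, trials, predictor="shuffle")
    shift = ss.ccg_shift_corrected(a, b, trials, predictor="shift")
    # both correctors remove the mean structure; totals agree coarsely
    assert shift.predictor == "shift"
    assert np.corrcoef(shuffle.ccg, shift.ccg)[0, 1] > 0.5 or (
        np.abs(shuffle.ccg).sum() < 1e-6
    )


def test_pair_swap_invariance(rng):
    a, b, trials = _pair(rng)
    r_ab = ss.spike_count_correlation(a, b, trials.assign(state="all"))
    r_ba = ss.spike_count_correlation(b, a, trials.assign(state="all"))
    assert r_ab["r_sc"] == r_ba["r_sc"]
    pair_ab = ss.ccg_shift_corrected(a, b, trials)
    pair_ba = ss.ccg_shift_corrected(b, a, trials)
    assert np.allclose(pair_ab.ccg, pair_ba.ccg[::-1], atol=1e-9)


def test_single_trial_raises(rng):
    a, b, trials = _pair(rng)
    with pytest.raises(SpikeStateError):
        ss.ccg_shift_corrected(a, b, trials.head(1))


def test_timescale_noiseless_recovery_and_flat_flag():
    t = np.linspace(0.01, 1.0, 40)
    r = 0.3 * (1.0 - np.exp(-t / 0.1))
    tau, info = fit_timescale(t, r)
    assert tau == pytest.approx(0.1, rel=0.01)
    assert info["reliable"]
    tau_flat, info_flat = fit_timescale(t, np.full_like(t, 0.3))
    assert not info_flat["reliable"]  # tau driven to the bound


def test_shared_gain_pair_rises_and_saturates():
    # common per-trial gain: correlation accumulates over the whole trial
    w = 0.35
    specs = (ss.UnitSpec("a", baseline_rate=20.0, tuning=(4, 0, 1, 0, 0),
                         shared_noise_weight=w),
             ss.UnitSpec("b", baseline_rate=18.0, tuning=(4, 0, 1, 0, 0),
                         shared_noise_weight=w))
    cfg = ss.SynthConfig(rng_seed=17, session_length=720.0, unit_specs=specs)
    trials = ss.generate_trials(cfg, "tf")
    import pandas as pd
    bouts = pd.DataFrame({"start": [0.0], "stop": [720.0], "state": ["stationary"]})
    trains, _ = ss.generate_spikes(cfg, trials, bouts)
    sub = trials[trials["stimulus_class"] == "tf_grating"]
    sub = sub[sub["parameter"] == 4.0]
    pair = ss.ccg_shift_corrected(trains[0], trains[1], sub)
    grid = np.array([0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0])
    r = ss.r_ccg(pair, grid)
    assert r[-1] > 0.15  # positive shared-gain correlation at full window
    assert r[-1] > r[0]  # grows with integration window


def test_identical_counts_give_unit_correlation(rng):
    trials = regular_trials(20, parameter=4.0)
    T = trials["onset"].iloc[-1] + 3.0
    a = poisson_train(rng, 20.0, T, 21.0, "a")
    b = SpikeTrain("b", np.clip(a.spike_times + 0.003, 0, T), T)
    res = ss.spike_count_correlation(a, b, trials.assign(state="all"),
                                     window=(0.1, 1.9))
    assert res["r_sc"] == pytest.approx(1.0, abs=0.02)


def test_zero_variance_condition_excluded():
    trials = regular_trials(12, parameter=4.0)
    T = trials["onset"].iloc[-1] + 3.0
    silent = SpikeTrain("a", np.empty(0), T)
    other = SpikeTrain("b", np.arange(0.05, T, 0.11), T)
    res = ss.spike_count_correlation(silent, other, trials.assign(state="all"))
    assert res["n_conditions"] == 0 and res["n_excluded"] == 1
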