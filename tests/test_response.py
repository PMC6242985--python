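"""F0/F1 estimation, ISI-permutation null, VEI, cycle averages."""

import numpy as np
import pandas as pd
import pytest

import spikestate as ss
from spikestate.core import SpikeTrain
from spikestate.response import (
    default_freq_of,
    permute_isi,
    permuted_f1_amplitudes,
    trial_f1_amplitudes,
)
from .conftest import inverse_cdf_train, poisson_train, regular_trials


def test_empty_train_zero_f0_f1():
    tr = SpikeTrain("u", np.empty(0), 10.0)
    f0, f1 = ss.per_trial_f0_f1(tr, 0.0, 2.0, 4.0)
    assert f0 == 0.0 and f1 == 0.0


def test_deterministic_density_recovers_rate_components():
    # spike density proportional to 10 + 5 cos(2 pi 4 t): F1/F0 = 0.5 exactly
    tr = inverse_cdf_train(lambda t: 10.0 + 5.0 * np.cos(2 * np.pi * 4.0 * t), 2.0, 4000)
    f0, f1 = ss.per_trial_f0_f1(tr, 0.0, 2.0, 4.0)
    assert abs(f1) / f0 == pytest.approx(0.5, rel=1e-3)


def test_f1_amplitude_shift_invariant_phase_rotates():
    rng = np.random.default_rng(0)
    # keep all shifted spikes inside the analysis window
    base = np.sort(rng.uniform(0.0, 1.9, 60))
    delta = 0.0625  # quarter cycle at 4 Hz
    a = SpikeTrain("a", base, 3.0)
    b = SpikeTrain("b", base + delta, 3.0)
    _, f1a = ss.per_trial_f0_f1(a, 0.0, 2.0, 4.0)
    _, f1b = ss.per_trial_f0_f1(b, delta, 2.0, 4.0)
    assert abs(f1a) == pytest.approx(abs(f1b), rel=1e-9)
    assert np.angle(f1b) == pytest.approx(np.angle(f1a), abs=1e-9)
    # keeping the window fixed instead rotates the phase by -2 pi f delta
    _, f1c = ss.per_trial_f0_f1(b, 0.0, 2.0, 4.0)
    expected = np.angle(f1a * np.exp(-2j * np.pi * 4.0 * delta))
    assert np.angle(f1c) == pytest.approx(expected, abs=1e-9)


def test_permute_isi_preserves_invariants(rng):
    t = np.sort(rng.uniform(0.0, 2.0, 40))
    p = permute_isi(t, rng)
    assert p.size == t.size
    assert p[0] == t[0]  # first-spike latency preserved
    assert np.allclose(np.sort(np.diff(p)), np.sort(np.diff(t)))
    single = np.array([0.7])
    assert np.array_equal(permute_isi(single, rng), single)


def test_permutation_destroys_locking_on_long_segment(rng):
    # one long strongly locked segment: permuted |F1| well below original
    T = 50.0
    tr = poisson_train(rng, lambda t: 10.0 + 5.0 * np.cos(2 * np.pi * 4.0 * t), T, 15.0)
    _, f1 = ss.per_trial_f0_f1(tr, 0.0, T, 4.0)
    trials = regular_trials(1, duration=T, gap=0.0)
    perm = permuted_f1_amplitudes(tr, trials, lambda r: 4.0, rng, n_perm=100)
    assert perm[0] < 0.25 * abs(f1)


def test_vei_null_below_threshold_locked_above(rng):
    trials = regular_trials(30, parameter=4.0)
    T_session = trials["onset"].iloc[-1] + 3.0
    null = poisson_train(rng, 20.0, T_session, 21.0, "null")

    def locked_rate(t):
        return 20.0 + 5.0 * np.cos(2 * np.pi * 4.0 * t)

    locked = poisson_train(rng, locked_rate, T_session, 26.0, "locked")
    v_null = ss.visual_evoked_index(null, trials, rng=rng, n_perm=50)
    v_locked = ss.visual_evoked_index(locked, trials, rng=rng, n_perm=50)
    assert not v_null.responsive
    assert v_locked.vei > v_null.vei
    assert v_locked.responsive


def test_normalized_f1_arithmetic_and_unlocked_near_one(rng):
    assert ss.normalized_f1(6.0, 2.0) == 3.0
    assert ss.normalized_f1(2.0, 2.0) == 1.0
    with pytest.raises(Exception):
        ss.normalized_f1(1.0, 0.0)
    trials = regular_trials(30, parameter=4.0)
    tr = poisson_train(rng, 20.0, trials["onset"].iloc[-1] + 3.0, 21.0)
    amps = trial_f1_amplitudes(tr, trials, lambda r: 4.0)
    perm = permuted_f1_amplitudes(tr, trials, lambda r: 4.0, rng, n_perm=50)
    assert ss.normalized_f1(amps.mean(), perm.mean()) == pytest.approx(1.0, abs=0.15)


def test_condition_summary_recovers_generator_amplitude():
    spec = ss.UnitSpec("u", baseline_rate=10.0, tuning=(4.0, 5.0, 1.0, 1.0, 1.0))
    cfg = ss.SynthConfig(rng_seed=21, session_length=720.0, unit_specs=(spec,))
    trials = ss.generate_trials(cfg, "tf").assign(state="stationary")
    bouts = pd.DataFrame({"start": [0.0], "stop": [720.0], "state": ["stationary"]})
    trains, _ = ss.generate_spikes(cfg, trials, bouts)
    summ = {s.condition: s for s in ss.condition_summary(
        trains[0], trials, state="stationary", min_trials=10)}
    pref = summ["tf_grating@4"]
    sem = pref.per_trial_f1.std(ddof=1) / np.sqrt(pref.n_trials)
    assert pref.f1_vector == pytest.approx(5.0, abs=3 * sem)
    sem_f0 = pref.per_trial_f0.std(ddof=1) / np.sqrt(pref.n_trials)
    assert pref.f0 == pytest.approx(10.0, abs=3 * sem_f0)


def test_condition_summary_min_trials_filter():
    spec = ss.UnitSpec("u", baseline_rate=10.0)
    cfg = ss.SynthConfig(rng_seed=1, session_length=720.0, unit_specs=(spec,))
    trials = ss.generate_trials(cfg, "tf").assign(state="stationary")
    bouts = pd.DataFrame({"start": [0.0], "stop": [720.0], "state": ["stationary"]})
    trains, _ = ss.generate_spikes(cfg, trials, bouts)
    nine = trials[trials["parameter"] == 4.0].head(9).copy()
    assert ss.condition_summary(trains[0], nine, state="stationary", min_trials=10) == []
    assert len(ss.condition_summary(trains[0], nine, state="stationary", min_trials=9)) == 1


def test_cycle_average_conserves_count_and_is_flat_for_poisson(rng):
    trials = regular_trials(40, parameter=4.0)
    T_session = trials["onset"].iloc[-1] + 3.0
    tr = poisson_train(rng, 20.0, T_session, 21.0)
    ca = ss.cycle_average(tr, trials, 4.0, n_bins=64)
    # conservation: smoothed rate integrates back to the raw spike count
    period = 1.0 / 4.0
    count = sum(tr.in_window(o, o + 2.0).size for o in trials["onset"])
    integral = ca.rate.sum() * (period / 64) * ca.n_cycles
    assert integral == pytest.approx(count, rel=1e-9)
    assert ca.rate.std() / ca.rate.mean() < 0.2  # no locking: flat within noise


def test_cycle_average_transient_on_peaks_early():
    spec = ss.UnitSpec("u", baseline_rate=2.0, tuning=(0.04, 20.0, 1.0, 1.0, 1.0),
                       cell_class="transient-ON")
    cfg = ss.SynthConfig(rng_seed=3, session_length=360.0, unit_specs=(spec,))
    trials = ss.generate_trials(cfg, "cr").assign(state="stationary")
    bouts = pd.DataFrame({"start": [0.0], "stop": [360.0], "state": ["stationary"]})
    trains, _ = ss.generate_spikes(cfg, trials, bouts)
    rev = trials[trials["stimulus_class"] == "contrast_reversal"]
    ca = ss.cycle_average(trains[0], rev, 1.0, n_bins=64)
    peak_bin = int(np.argmax(ca.rate))
    assert peak_bin < 8  # first quarter of the ON half-cycle


def test_f0_additivity_over_partition(rng):
    tr = poisson_train(rng, 15.0, 10.0, 16.0)
    f0_whole, _ = ss.per_trial_f0_f1(tr, 1.0, 2.0, 1.0)
    f0_a, _ = ss.per_trial_f0_f1(tr, 1.0, 1.0, 1.0)
    f0_b, _ = ss.per_trial_f0_f1(tr, 2.0, 1.0, 1.0)
    assert f0_whole == pytest.approx((f0_a + f0_b) / 2, rel=1e-12)
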