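"""SF-shape clustering, ON/OFF classification, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import spikestate as ss
from spikestate.celltyping import blank_rate_stats, isi_fraction_below
from spikestate.core import SpikeStateError
from spikestate.response import CycleAverage


def _cycle(rate: np.ndarray, cond="c", freq=2.0) -> CycleAverage:
    n = rate.size
    return CycleAverage("u", cond, "stationary", freq,
                        np.linspace(0, 1, n + 1), rate.astype(float), 40, 0.002)


SFS = (0.01, 0.02, 0.04, 0.08, 0.16)


def _feature_inputs(scale=1.0, stim_level=10.0, blank_level=2.0):
    cycles = {sf: _cycle(scale * np.full(64, stim_level)) for sf in SFS}
    cycles["blank"] = _cycle(scale * np.full(64, blank_level))
    return cycles


def test_feature_vector_normalization_and_scale_invariance():
    v1 = ss.sf_feature_vector(_feature_inputs(1.0), SFS)
    v9 = ss.sf_feature_vector(_feature_inputs(9.0), SFS)
    assert v1.max() == 1.0
    assert np.allclose(v1, v9, atol=1e-9)


def test_suppressed_unit_returns_none_and_missing_raises():
    assert ss.sf_feature_vector(
        _feature_inputs(stim_level=1.0, blank_level=5.0), SFS) is None
    incomplete = _feature_inputs()
    del incomplete[0.16]
    with pytest.raises(SpikeStateError):
        ss.sf_feature_vector(incomplete, SFS)


def _template_families(rng, n_per=20, noise=0.05):
    """Three SF-response families as feature vectors (6 x 64 bins)."""
    phase = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    feats, labels, ids = [], [], []
    for i in range(3 * n_per):
        fam = i // n_per
        segs = []
        for k, _ in enumerate(SFS):
            if fam == 0:  # nonlinear-highSF: strong elevation at top 2 SFs
                level = 2.0 + (8.0 if k >= 3 else 0.0)
                seg = level + 1.5 * np.cos(2 * phase)
            elif fam == 1:  # mid-SF tuned F1
                amp = [2, 6, 10, 4, 1][k]
                seg = 2.0 + amp * np.clip(np.cos(phase), 0, None)
            else:  # high baseline, weak tuning
                seg = 12.0 + 1.0 * np.cos(phase)
            segs.append(seg)
        blank = np.full(64, 12.0 if fam == 2 else 2.0)
        vec = np.concatenate(segs + [blank])
        vec = vec + rng.normal(0, noise * vec.max(), vec.size)
        feats.append(np.clip(vec, 0, None) / np.clip(vec, 0, None).max())
        labels.append(fam)
        ids.append(f"u{i}")
    return np.array(feats), np.array(labels), ids


def test_kmeans_recovers_template_families(rng):
    X, truth, ids = _template_families(rng)
    assign = ss.kmeans_groups(X, ids, k=3, seed=0)
    got = np.array([assign[u].sf_group for u in ids])
    assert adjusted_rand_score(truth, got) == 1.0
    # canonical numbering: the high-SF-elevated family is Group 1
    assert set(got[truth == 0]) == {1}


def test_kmeans_order_invariance_and_degenerate_k(rng):
    X, truth, ids = _template_families(rng, n_per=5)
    a = ss.kmeans_groups(X, ids, k=3, seed=0)
    perm = rng.permutation(len(ids))
    b = ss.kmeans_groups(X[perm], [ids[i] for i in perm], k=3, seed=0)
    assert all(a[u].sf_group == b[u].sf_group for u in ids)
    each_own = ss.kmeans_groups(X[:4], ids[:4], k=4, seed=0)
    assert len({v.sf_group for v in each_own.values()}) == 4


def test_kmeans_degenerate_features_rejected():
    X = np.ones((10, 384))
    with pytest.raises(SpikeStateError):
        ss.kmeans_groups(X, [f"u{i}" for i in range(10)], k=3)


def _reversal_cycle(kind: str, n=64, amp=20.0, base=2.0):
    ph = np.arange(n) / n  # one 1-s cycle; ON half first
    tau = {"transient": 0.05, "sustained": 0.4}[kind.split("-")[0]]
    half = ph < 0.5
    decay_on = np.exp(-(ph % 0.5) / tau)
    rate = np.full(n, base)
    if kind.endswith("ON"):
        rate[half] += amp * decay_on[half]
    elif kind.endswith("OFF"):
        rate[~half] += amp * decay_on[~half]
    else:  # ON-OFF
        rate += amp * decay_on
    return rate


def test_onoff_generator_label_recovery(rng):
    kinds = ["transient-ON", "sustained-ON", "transient-OFF", "sustained-OFF"]
    cycles, stats, truth = {}, {}, {}
    i = 0
    for kind in kinds:
        for _ in range(20):
            uid = f"u{i:03d}"; i += 1
            rate = _reversal_cycle(kind) * rng.uniform(0.7, 1.3)
            rate = rate + rng.normal(0, 0.3, rate.size)
            cycles[uid] = _cycle(np.clip(rate, 0, None), freq=1.0)
            stats[uid] = (2.0, 1.0)
            truth[uid] = kind
    out = ss.onoff_classify(cycles, stats, seed=0, min_cycles=30)
    acc = np.mean([out[u].onoff_class == truth[u] for u in truth])
    assert acc >= 0.95


def test_onoff_both_phases_excluded_flat_unclassified():
    cycles = {"both": _cycle(_reversal_cycle("transient-BOTH"), freq=1.0),
              "flat": _cycle(np.full(64, 2.0), freq=1.0),
              "on": _cycle(_reversal_cycle("transient-ON"), freq=1.0),
              "off": _cycle(_reversal_cycle("sustained-OFF"), freq=1.0)}
    stats = {u: (2.0, 1.0) for u in cycles}
    out = ss.onoff_classify(cycles, stats, seed=0, min_cycles=30)
    assert out["both"].onoff_class == "excluded-ON-OFF"
    assert out["flat"].onoff_class == "unclassified"
    assert out["on"].onoff_class.endswith("ON")
    assert out["off"].onoff_class.endswith("OFF")


def test_group_comparison_identical_shifted_and_undersized(rng):
    mi = {f"a{i}": float(v) for i, v in enumerate(rng.normal(0.1, 0.1, 30))}
    mi.update({f"b{i}": mi[f"a{i}"] for i in range(30)})  # identical samples
    groups = {u: ("A" if u.startswith("a") else "B") for u in mi}
    out = ss.group_modulation_comparison(groups, mi)
    assert out["ks_p"].loc["A", "B"] == 1.0

    mi2 = {f"a{i}": float(v) for i, v in enumerate(rng.normal(0.4, 0.1, 30))}
    mi2.update({f"b{i}": float(v) for i, v in enumerate(rng.normal(0.05, 0.1, 30))})
    out = ss.group_modulation_comparison(groups, mi2)
    assert out["ks_p"].loc["A", "B"] < 0.01
    assert out["median_mi"]["A"] > out["median_mi"]["B"]

    small = {u: g for u, g in groups.items() if g == "B" or u in list(mi)[:4]}
    tiny_groups = {**{f"a{i}": "A" for i in range(4)}, **{f"b{i}": "B" for i in range(30)}}
    out = ss.group_modulation_comparison(tiny_groups, mi2)
    assert np.isnan(out["ks_p"].loc["A", "B"])


def test_blank_stats_and_isi_fraction(rng):
    from .conftest import poisson_train, regular_trials
    trials = regular_trials(10, stimulus_class="blank", parameter=np.nan)
    T = trials["onset"].iloc[-1] + 3.0
    tr = poisson_train(rng, 20.0, T, 21.0)
    mu, sd = blank_rate_stats(tr, trials, 1.0 / 64)
    assert mu == pytest.approx(20.0, rel=0.15)
    frac = isi_fraction_below(tr, 0.010)
    assert frac == pytest.approx(1 - np.exp(-20 * 0.01), abs=0.05)
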