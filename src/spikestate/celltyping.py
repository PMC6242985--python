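"""Functional cell typing from cycle-average response shapes.

Two groupings of dLGN units, both computed from stationary-state data only:

* **SF groups** -- k-means (k = 3) on the concatenation of a unit's
  normalized cycle averages across the five spatial-frequency conditions and
  the blank. Units suppressed by the stimulus (mean stimulus-driven rate
  below the blank rate) are excluded. Cluster labels are re-ordered by a
  canonical key -- the mean normalized response in the highest-SF segment
  minus the blank segment, descending -- so that Group 1 is the
  nonlinear-high-SF-like cluster across runs and seeds.

* **ON/OFF classes** -- units driven by full-field 1 Hz contrast reversal
  are partitioned (k-means, k = 4) on their normalized reversal cycle
  averages. Units whose ON *and* OFF half-cycle peaks both exceed the blank
  rate by 3 blank SDs are excluded as ON-OFF; units with neither half driven
  are unclassified. Clusters are named by the driven half-cycle (ON/OFF)
  and a transience index (peak over late-plateau rate of the driven half):
  within a polarity the higher-index cluster is transient, the lower
  sustained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core import SpikeStateError, SpikeTrain
from .response import CycleAverage

__all__ = [
    "CellTypeAssignment",
    "sf_feature_vector",
    "kmeans_groups",
    "onoff_classify",
    "group_modulation_comparison",
]

ONOFF_CLASSES = ("transient-ON", "sustained-ON", "transient-OFF", "sustained-OFF")
TRANSIENCE_NAMING_THRESHOLD = 2.0  # peak/plateau ratio separating the names


@dataclass
class CellTypeAssignment:
    unit_id: str
    sf_group: int | str | None = None  # 1..k or "excluded-suppressed"
    onoff_class: str | None = None  # one of ONOFF_CLASSES, "excluded-ON-OFF", "unclassified"
    feature: np.ndarray | None = None
    centroid_distance: float = float("nan")


def sf_feature_vector(
    cycles: dict[float | str, CycleAverage],
    sf_order: tuple[float, ...],
    blank_key: str = "blank",
) -> np.ndarray | None:
    """Concatenated, peak-normalized cycle averages (5 SFs + blank).

    Returns None for suppressed units (mean rate over the SF conditions
    below the blank mean rate); raises if a condition is missing.
    """
    missing = [k for k in (*sf_order, blank_key) if k not in cycles]
    if missing:
        raise SpikeStateError(f"missing cycle averages for {missing}")
    stim = np.concatenate([cycles[sf].rate for sf in sf_order])
    blank = cycles[blank_key].rate
    if stim.mean() < blank.mean():
        return None  # suppressed by the stimulus
    vec = np.concatenate([stim, blank])
    peak = vec.max()
    if peak <= 0:
        return None
    return vec / peak


def kmeans_groups(
    features: np.ndarray,
    unit_ids: list[str],
    *,
    k: int = 3,
    n_init: int = 50,
    seed: int = 0,
    n_bins: int = 64,
) -> dict[str, CellTypeAssignment]:
    """K-means on SF feature vectors with canonical group numbering.

    ``features`` is (n_units, 6 * n_bins) as built by
    :func:`sf_feature_vector`. Groups are renumbered 1..k by descending
    (highest-SF segment mean - blank segment mean) of the cluster centroid,
    which puts the nonlinear-high-SF-like cluster first.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < k:
        raise SpikeStateError(f"k-means needs >= k={k} units")
    if np.allclose(X, X[0]):
        raise SpikeStateError("degenerate features: all units identical")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    cent = km.cluster_centers_
    # canonical key per cluster: high-SF segment minus blank segment
    hi_sf = cent[:, 4 * n_bins : 5 * n_bins].mean(axis=1)
    blank = cent[:, 5 * n_bins : 6 * n_bins].mean(axis=1)
    order = np.argsort(-(hi_sf - blank), kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    dists = np.linalg.norm(X - cent[raw], axis=1)
    return {
        uid: CellTypeAssignment(
            unit_id=uid, sf_group=relabel[int(g)], feature=x, centroid_distance=float(d)
        )
        for uid, g, x, d in zip(unit_ids, raw, X, dists)
    }


def blank_rate_stats(
    train: SpikeTrain, blank_trials: pd.DataFrame, bin_width: float
) -> tuple[float, float]:
    """Mean and SD of binned blank-epoch firing rates (spikes/s)."""
    rates = []
    for _, row in blank_trials.iterrows():
        n_bins = int(row["duration"] / bin_width)
        t = train.in_window(row["onset"], row["onset"] + n_bins * bin_width) - row["onset"]
        counts = np.histogram(t, bins=n_bins, range=(0, n_bins * bin_width))[0]
        rates.append(counts / bin_width)
    r = np.concatenate(rates) if rates else np.zeros(1)
    return float(r.mean()), float(r.std(ddof=1)) if r.size > 1 else 0.0


def _transience_index(rate_half: np.ndarray) -> float:
    peak = float(rate_half.max())
    plateau = float(rate_half[-rate_half.size // 4 :].mean())
    return peak / plateau if plateau > 0 else np.inf


def onoff_classify(
    cycles: dict[str, CycleAverage],
    blank_stats: dict[str, tuple[float, float] | float],
    *,
    k: int = 4,
    n_init: int = 50,
    seed: int = 0,
    min_cycles: int = 50,
    sd_factor: float = 4.0,
) -> dict[str, CellTypeAssignment]:
    """Classify units from 1 Hz contrast-reversal cycle averages.

    ``cycles`` maps unit id to its reversal cycle average (stationary
    trials); ``blank_stats`` maps unit id to its blank mean rate (a bare
    float, or the (mean, SD) pair from :func:`blank_rate_stats`, of which
    the mean is used). A half-cycle counts as driven when its peak exceeds
    the blank mean by ``sd_factor`` standard errors of a cycle-average bin
    under the blank rate -- for a Poisson blank of rate mu, a bin of width
    w averaged over C cycles has SE sqrt(mu / (w C)), which is the noise
    scale the cycle-average peak is actually measured at. The default of 4
    accounts for the peak being a maximum over ~32 half-cycle bins: at 3 SE
    a Poisson-flat half crosses threshold in a few percent of units, at 4
    SE in ~0.1%.
    """
    out: dict[str, CellTypeAssignment] = {}
    eligible: list[str] = []
    feats: list[np.ndarray] = []
    for uid, ca in cycles.items():
        if ca.n_cycles < min_cycles:
            raise SpikeStateError(f"unit {uid}: needs >= {min_cycles} reversal cycles")
        stat = blank_stats[uid]
        mu = float(stat[0]) if isinstance(stat, tuple) else float(stat)
        bin_dur = 1.0 / (ca.cycle_freq * ca.rate.size)
        se = np.sqrt(max(mu, 0.5) / (bin_dur * ca.n_cycles))
        thresh = mu + sd_factor * se
        half = ca.rate.size // 2
        on_peak, off_peak = ca.rate[:half].max(), ca.rate[half:].max()
        if on_peak > thresh and off_peak > thresh:
            out[uid] = CellTypeAssignment(uid, onoff_class="excluded-ON-OFF")
        elif on_peak <= thresh and off_peak <= thresh:
            out[uid] = CellTypeAssignment(uid, onoff_class="unclassified")
        else:
            eligible.append(uid)
            feats.append(ca.rate / ca.rate.max())
    if not eligible:
        return out
    X = np.vstack(feats)
    kk = min(k, len(eligible))
    km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    cent = km.cluster_centers_
    half = X.shape[1] // 2

    # name clusters by (polarity of the driven half, transience rank)
    info = []
    for c in range(kk):
        on_half, off_half = cent[c, :half], cent[c, half:]
        is_on = on_half.max() >= off_half.max()
        driven = on_half if is_on else off_half
        info.append((c, "ON" if is_on else "OFF", _transience_index(driven)))
    names: dict[int, str] = {}
    for pol in ("ON", "OFF"):
        members = sorted(
            [i for i in info if i[1] == pol], key=lambda i: -i[2]
        )
        if len(members) == 2:
            names[members[0][0]] = f"transient-{pol}"
            names[members[1][0]] = f"sustained-{pol}"
        else:
            for c, _, ti in members:
                kind = "transient" if ti > TRANSIENCE_NAMING_THRESHOLD else "sustained"
                key = f"{kind}-{pol}"
                # avoid duplicate names when >2 clusters share a polarity
                while key in names.values():
                    kind = "sustained" if kind == "transient" else "transient"
                    key = f"{kind}-{pol}"
                names[c] = key
    dists = np.linalg.norm(X - cent[raw], axis=1)
    for uid, g, x, d in zip(eligible, raw, X, dists):
        out[uid] = CellTypeAssignment(
            uid, onoff_class=names[int(g)], feature=x, centroid_distance=float(d)
        )
    return out


def group_modulation_comparison(
    groups: dict[str, int | str],
    mi_by_unit: dict[str, float],
    *,
    min_group: int = 5,
    isi_frac_by_unit: dict[str, float] | None = None,
    baseline_by_unit: dict[str, float] | None = None,
) -> dict:
    """Group-wise MI distributions and pairwise two-sample K-S tests.

    ``groups`` maps unit id to its group label (excluded/unclassified units
    should already be absent). Pairs where either group has fewer than
    ``min_group`` units are flagged unavailable (NaN p). Optional per-unit
    controls (baseline rate, fraction of ISIs < 10 ms) are summarised per
    group when provided.
    """
    by_group: dict[str | int, list[float]] = {}
    for uid, g in groups.items():
        if uid in mi_by_unit and np.isfinite(mi_by_unit[uid]):
            by_group.setdefault(g, []).append(mi_by_unit[uid])
    labels = sorted(by_group, key=str)
    ks_p = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    ks_stat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, ga in enumerate(labels):
        for gb in labels[i:]:
            a, b = np.array(by_group[ga]), np.array(by_group[gb])
            if a.size < min_group or b.size < min_group:
                continue
            if ga == gb or np.array_equal(np.sort(a), np.sort(b)):
                s, p = 0.0, 1.0
            else:
                res = stats.ks_2samp(a, b)
                s, p = float(res.statistic), float(res.pvalue)
            ks_p.loc[ga, gb] = ks_p.loc[gb, ga] = p
            ks_stat.loc[ga, gb] = ks_stat.loc[gb, ga] = s
    result = {
        "mi": {g: np.sort(np.array(v)) for g, v in by_group.items()},
        "median_mi": {g: float(np.median(v)) for g, v in by_group.items()},
        "ks_p": ks_p,
        "ks_statistic": ks_stat,
    }
    for name, extra in (
        ("baseline_rate", baseline_by_unit),
        ("isi_lt_10ms_fraction", isi_frac_by_unit),
    ):
        if extra is not None:
            result[name] = {
                g: float(np.mean([extra[u] for u, gg in groups.items() if gg == g and u in extra]))
                for g in labels
            }
    return result


def isi_fraction_below(train: SpikeTrain, threshold: float = 0.010) -> float:
    """Fraction of inter-spike intervals shorter than ``threshold`` seconds."""
    if len(train) < 2:
        return float("nan")
    isis = np.diff(train.spike_times)
    return float(np.mean(isis < threshold))
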