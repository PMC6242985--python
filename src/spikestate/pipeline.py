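"""End-to-end orchestration of the analysis battery.

Stages run in the order classify -> respond -> modulate / variability /
correlate / tune -> typecells, mirroring how the analyses build on each
other. A run is fully determined by its :class:`RunConfig`: one global seed
is expanded into per-stage child seeds keyed by stage name, so toggling one
stage never reshuffles another. Every unit-level exclusion (non-responsive,
too few trials, suppressed, ON-OFF, poor tuning fit) is counted in the run
manifest, which also records a config hash and input checksums so reruns
can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import celltyping as ct
from . import correlation as corr
from . import io as sio
from . import modulation as mod
from . import response as resp
from . import tuning as tun
from . import variability as var
from .core import SpikeStateError, condition_key

STAGES = ("classify", "respond", "modulate", "variability", "correlate", "tune", "typecells")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    experiment: str  # tf | sf | cr
    spikes: str
    trials: str
    behavior: str
    out_dir: str
    seed: int = 0
    loco_thresh: float = 1.0
    stat_thresh: float = 0.25
    occupancy: float = 0.80
    min_trials: int = 4
    min_trials_variability: int = 10
    n_perm: int = 100
    vei_threshold: float = 2.0
    sf_drift_tf: float = 2.0
    goodness_min: float = 0.90
    max_pairs: int = 50
    stages: tuple[str, ...] = STAGES

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Raises on validation failure; writes per-stage TSVs, ``manifest.json``
    and a short ``report.md``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = sio.validate_inputs(config.spikes, config.trials, config.behavior)
    if report["errors"]:
        raise SpikeStateError("input validation failed: " + "; ".join(report["errors"]))

    trace = sio.read_behavior(config.behavior)
    trials = sio.read_trials(config.trials)
    span = trace.span[1]
    trains = sio.read_spikes(config.spikes, span)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "inputs": {p: _checksum(getattr(config, p)) for p in ("spikes", "trials", "behavior")},
        "stages": {},
        "exclusions": {},
    }
    lines = [f"# spikestate run ({config.experiment} experiment)", ""]

    # ---- classify -------------------------------------------------------
    if "classify" in config.stages:
        trials = beh.classify_trials(
            trace, trials, config.loco_thresh, config.stat_thresh, config.occupancy
        )
        sio.write_trials(out / "trials_labeled.tsv", trials)
        counts = trials["state"].value_counts().to_dict()
        manifest["stages"]["classify"] = {"n_trials": len(trials), "by_state": counts}
        lines += [f"Trials: {len(trials)} ({counts})", ""]

    # ---- respond: per-state condition summaries + responsiveness --------
    summaries: dict[str, dict[str, list[resp.ResponseSummary]]] = {}
    responsive: dict[str, bool] = {}
    if "respond" in config.stages:
        rng = np.random.default_rng(config.stage_seed("respond"))
        n_in = len(trains)
        for tr in trains:
            vei = resp.visual_evoked_index(
                tr, trials, rng=rng, n_perm=config.n_perm,
                sf_drift_tf=config.sf_drift_tf, threshold=config.vei_threshold,
            )
            responsive[tr.unit_id] = vei.responsive
        kept = [tr for tr in trains if responsive[tr.unit_id]]
        manifest["exclusions"]["non_responsive"] = n_in - len(kept)
        all_rows = []
        for tr in kept:
            summaries[tr.unit_id] = {}
            for state in ("stationary", "locomotion"):
                s = resp.condition_summary(
                    tr, trials, state=state, min_trials=config.min_trials,
                    sf_drift_tf=config.sf_drift_tf, rng=rng, n_perm=config.n_perm,
                )
                summaries[tr.unit_id][state] = s
                all_rows += s
        frame = resp.summaries_to_frame(all_rows)
        frame.to_csv(out / "responses.tsv", sep="\t", index=False)
        manifest["stages"]["respond"] = {"units_in": n_in, "units_out": len(kept)}
        lines += [f"Responsive units (VEI > {config.vei_threshold} spikes/s): "
                  f"{len(kept)}/{n_in}", ""]
        trains = kept

    # ---- modulate -------------------------------------------------------
    mod_rows = []
    if "modulate" in config.stages and summaries:
        for uid, per_state in summaries.items():
            for measure, attr in (("F0", "f0"), ("F1", "f1_amp")):
                stat = {s.condition: getattr(s, attr) for s in per_state.get("stationary", [])
                        if s.stimulus_class != "blank"}
                loco = {s.condition: getattr(s, attr) for s in per_state.get("locomotion", [])
                        if s.stimulus_class != "blank"}
                common = sorted(set(stat) & set(loco))
                if len(common) < 2:
                    continue
                try:
                    r = mod.modulation_index(
                        np.array([stat[c] for c in common]),
                        np.array([loco[c] for c in common]),
                        unit_id=uid, measure=measure,
                    )
                except SpikeStateError:
                    continue
                mod_rows.append({"unit_id": uid, "measure": measure, "slope": r.slope,
                                 "MI": r.mi, "n_conditions": r.n_conditions})
        pd.DataFrame(mod_rows).to_csv(out / "modulation.tsv", sep="\t", index=False)
        manifest["stages"]["modulate"] = {"n_results": len(mod_rows)}

    # ---- variability ----------------------------------------------------
    if "variability" in config.stages and summaries:
        var_rows = []
        for tr in trains:
            for state in ("stationary", "locomotion"):
                per_f1 = {
                    s.condition: s.per_trial_f1
                    for s in summaries.get(tr.unit_id, {}).get(state, [])
                    if s.stimulus_class != "blank"
                }
                v = var.unit_variability(
                    tr, trials, per_f1, state=state,
                    min_trials=config.min_trials_variability,
                )
                if v is not None:
                    var_rows.append({"unit_id": v.unit_id, "state": v.state, "fano": v.fano,
                                     "f1_var": v.f1_variance, "f1_cv": v.f1_cv})
        pd.DataFrame(var_rows).to_csv(out / "variability.tsv", sep="\t", index=False)
        manifest["stages"]["variability"] = {"n_results": len(var_rows)}

    # ---- correlate ------------------------------------------------------
    if "correlate" in config.stages and len(trains) >= 2:
        pairs = [
            (a, b)
            for i, a in enumerate(trains)
            for b in trains[i + 1 :]
        ][: config.max_pairs]
        corr_rows = []
        for a, b in pairs:
            for state in ("stationary", "locomotion"):
                sub = trials[(trials["state"] == state) & (trials["stimulus_class"] != "blank")]
                r = corr.spike_count_correlation(
                    a, b, sub, min_trials=config.min_trials_variability
                )
                if r["n_conditions"]:
                    corr_rows.append({"unit_i": a.unit_id, "unit_j": b.unit_id,
                                      "state": state, "r_sc": r["r_sc"], "se": r["se"],
                                      "n_conditions": r["n_conditions"]})
        pd.DataFrame(corr_rows).to_csv(out / "correlations.tsv", sep="\t", index=False)
        manifest["stages"]["correlate"] = {"n_pairs": len(pairs), "n_results": len(corr_rows)}

    # ---- tune -----------------------------------------------------------
    if "tune" in config.stages and summaries and config.experiment in ("tf", "sf"):
        domain = "TF" if config.experiment == "tf" else "SF"
        fit_rows = []
        n_excluded = 0
        for uid, per_state in summaries.items():
            for state in ("stationary", "locomotion"):
                pts = [(s.parameter, s.f1_amp) for s in per_state.get(state, [])
                       if s.stimulus_class != "blank"]
                if len(pts) < 5:
                    continue
                pts.sort()
                fit = tun.fit_two_gaussian(
                    np.array([p for p, _ in pts]), np.array([r for _, r in pts]),
                    unit_id=uid, state=state, domain=domain,
                    goodness_min=config.goodness_min,
                )
                n_excluded += int(fit.excluded)
                fit_rows.append({"unit_id": uid, "state": state, "domain": domain,
                                 "p": fit.p, "a": fit.a, "s": fit.s, "b1": fit.b1,
                                 "b2": fit.b2, "goodness": fit.goodness,
                                 "bandwidth": fit.bandwidth, "excluded": fit.excluded})
        pd.DataFrame(fit_rows).to_csv(out / "tuning.tsv", sep="\t", index=False)
        manifest["stages"]["tune"] = {"n_fits": len(fit_rows)}
        manifest["exclusions"]["poor_tuning_fit"] = n_excluded

    # ---- typecells ------------------------------------------------------
    if "typecells" in config.stages and config.experiment in ("sf", "cr"):
        seed = config.stage_seed("typecells")
        type_rows = []
        if config.experiment == "sf":
            sf_order = tuple(sorted(
                trials.loc[trials["stimulus_class"] == "sf_grating", "parameter"].dropna().unique()
            ))
            stat_trials = trials[trials["state"] == "stationary"]
            feats, ids = [], []
            n_suppressed = 0
            for tr in trains:
                cycles: dict[float | str, resp.CycleAverage] = {}
                for sf in sf_order:
                    sub = stat_trials[(stat_trials["stimulus_class"] == "sf_grating")
                                      & (stat_trials["parameter"] == sf)]
                    if sub.empty:
                        break
                    cycles[sf] = resp.cycle_average(tr, sub, config.sf_drift_tf,
                                                    state="stationary")
                blanks = stat_trials[stat_trials["stimulus_class"] == "blank"]
                if len(cycles) < len(sf_order) or blanks.empty:
                    continue
                cycles["blank"] = resp.cycle_average(tr, blanks, config.sf_drift_tf,
                                                     state="stationary")
                vec = ct.sf_feature_vector(cycles, sf_order)
                if vec is None:
                    n_suppressed += 1
                    continue
                feats.append(vec)
                ids.append(tr.unit_id)
            manifest["exclusions"]["suppressed"] = n_suppressed
            if len(ids) >= 3:
                assign = ct.kmeans_groups(np.vstack(feats), ids, seed=seed)
                type_rows = [{"unit_id": u, "sf_group": a.sf_group,
                              "centroid_distance": a.centroid_distance}
                             for u, a in assign.items()]
        else:  # contrast reversal
            stat_trials = trials[trials["state"] == "stationary"]
            rev = stat_trials[stat_trials["stimulus_class"] == "contrast_reversal"]
            blanks = stat_trials[stat_trials["stimulus_class"] == "blank"]
            if not rev.empty and not blanks.empty:
                freq = float(rev["parameter"].iloc[0])
                bin_dur = 1.0 / (freq * 64)
                cycles = {tr.unit_id: resp.cycle_average(tr, rev, freq, state="stationary")
                          for tr in trains}
                stats_ = {tr.unit_id: ct.blank_rate_stats(tr, blanks, bin_dur)
                          for tr in trains}
                assign = ct.onoff_classify(cycles, stats_, seed=seed,
                                           min_cycles=min(50, 2 * len(rev)))
                type_rows = [{"unit_id": u, "onoff_class": a.onoff_class,
                              "centroid_distance": a.centroid_distance}
                             for u, a in assign.items()]
                manifest["exclusions"]["on_off"] = sum(
                    1 for a in assign.values() if a.onoff_class == "excluded-ON-OFF"
                )
        pd.DataFrame(type_rows).to_csv(out / "celltypes.tsv", sep="\t", index=False)
        manifest["stages"]["typecells"] = {"n_assigned": len(type_rows)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    lines += ["## Manifest", "```json", json.dumps(manifest, indent=2, sort_keys=True), "```"]
    (out / "report.md").write_text("\n".join(lines))
    return out
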