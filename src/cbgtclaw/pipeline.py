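"""End-to-end orchestration: simulate -> CLAW -> ensembles -> DDM -> stats.

A run is driven by a plain configuration dictionary (YAML-friendly) with a
single master seed; every stage derives its own seeds from it, so a rerun
with the same configuration reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import claw as claw_mod
from . import ddm as ddm_mod
from . import ensembles as ens_mod
from . import io as io_mod
from . import stats as stats_mod
from . import synth
from .errors import ConfigurationError

log = logging.getLogger("cbgtclaw")

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "cbgtclaw_run",
    "n_networks": 10,
    "jitter_scale": 0.05,
    "stages": [0, 1, 3, 8, 15, 30],
    "n_pre": 50,
    "n_post": 50,
    "claw": {"bin_width_ms": 10.0, "min_edge_prob": 0.01, "min_visits": 20},
    "ddm": {"n_sim": 20000, "trajectory": ["I", "II", "III"]},
    "stats": {"window_ms": 50.0},
}

_REQUIRED = ("seed", "out_dir")


def validate_config(config: dict) -> dict:
    """Merge with defaults and validate; unknown or missing keys are named."""
    unknown = set(config) - set(DEFAULTS)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in config]
    if missing:
        raise ConfigurationError(f"missing required configuration keys: {missing}")
    merged = {**DEFAULTS, **config}
    for sub in ("claw", "ddm", "stats"):
        bad = set(merged[sub]) - set(DEFAULTS[sub])
        if bad:
            raise ConfigurationError(f"unknown keys in '{sub}': {sorted(bad)}")
        merged[sub] = {**DEFAULTS[sub], **merged[sub]}
    if not isinstance(merged["seed"], int) or merged["seed"] < 0:
        raise ConfigurationError("seed must be a non-negative integer")
    return merged


def _stage_seed(master: int, network: int, stage: int) -> int:
    return (master * 100003 + network * 7919 + stage * 104729 + 17) % (2 ** 31)


def _session(cfg, master, net, stage, n_pre, n_post, store_rates):
    plan = synth.SessionPlan(
        n_train=stage,
        n_pre=n_pre,
        n_post=n_post,
        seed=_stage_seed(master, net, stage),
    )
    return synth.run_session(cfg, plan, store_rates=store_rates)


def pipeline_run(config: dict) -> Path:
    """Execute the five stages and write all artifacts to the output
    directory; returns that directory."""
    cfg = validate_config(config)
    seed = cfg["seed"]
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    base = synth.default_config()
    nets = [
        synth.sample_network(base, cfg["jitter_scale"], seed + 7 * i)
        for i in range(cfg["n_networks"])
    ]
    outputs: list[str] = []

    # ---- pass 1: pre-learning trials -> CLAW + control ensembles ---------
    log.info("pass 1: baseline sessions for CLAW and CCA")
    pre_trials: list = []
    activity, ddm_rows, behavior_frames = [], [], []
    for i, net_cfg in enumerate(nets):
        recs = _session(net_cfg, seed, i, 0, cfg["n_pre"], 0, store_rates=True)
        behavior_frames.append(io_mod.behavior_to_frame(recs).assign(network=i, stage_run=0))
        decided = [r for r in recs if r.decided]
        pre_trials.extend(decided)
        activity.append(
            np.mean([ens_mod.summarize_activity(r.decision_rates) for r in decided], axis=0)
        )
        fit = ddm_mod.fit_static(
            [r.choice for r in decided],
            np.array([r.decision_time for r in decided]) / 1000.0,
            np.array([r.consolidation_time for r in decided]) / 1000.0,
            include_consolidation=True,
        )
        p = fit.params
        ddm_rows.append([p.a, p.v, p.tr, p.z])

    cm = claw_mod.ClawModel(**{
        "bin_width_ms": cfg["claw"]["bin_width_ms"],
        "min_edge_prob": cfg["claw"]["min_edge_prob"],
        "min_visits": cfg["claw"]["min_visits"],
    }).fit(pre_trials)
    (out / "claw_model.json").write_text(cm.to_json())
    outputs.append("claw_model.json")

    cca = ens_mod.ControlEnsembleCCA().fit(np.array(activity), np.array(ddm_rows))
    loadings = pd.DataFrame(
        cca.loadings_.U, index=ens_mod.ACTIVITY_ELEMENTS, columns=cca.loadings_.labels
    )
    loadings.to_csv(out / "loadings_activity.csv")
    pd.DataFrame(
        cca.loadings_.V, index=ens_mod.DDM_PARAMS, columns=cca.loadings_.labels
    ).to_csv(out / "loadings_ddm.csv")
    outputs += ["loadings_activity.csv", "loadings_ddm.csv"]

    # ---- pass 2: learning stages -> zone tables + engagement table -------
    log.info("pass 2: learning stages")
    zone_tables: dict[int, pd.DataFrame] = {}
    engagement_rows = []
    class_rows = []
    n_bins = int(round(cfg["stats"]["window_ms"] / cfg["claw"]["bin_width_ms"]))
    for stage in cfg["stages"]:
        stage_seqs = []
        for i, net_cfg in enumerate(nets):
            recs = _session(net_cfg, seed, i, stage, 0, cfg["n_post"], store_rates=True)
            post = [r for r in recs if r.block == "post" and r.decided]
            behavior_frames.append(
                io_mod.behavior_to_frame(recs).assign(network=i, stage_run=stage)
            )
            stage_seqs.extend(cm._trial_sequence(t) for t in post)
            paths = cm.transform(post)
            for p_, r in zip(paths, post):
                class_rows.append(
                    {"network": i, "stage": stage,
                     "trajectory": "->".join(p_),
                     "class": claw_mod.classify_trajectory(p_)}
                )
            # launching-window engagement of the choice ensemble
            for r in post:
                tc = cca.transform(r, cfg["claw"]["bin_width_ms"])
                for b in range(min(n_bins, tc.W.shape[0])):
                    engagement_rows.append(
                        {
                            "network_id": i,
                            "trajectory_type": "L" if r.choice == "L" else "R",
                            "learning_stage": stage,
                            "time_bin": b,
                            "value": tc.W[b, 0],
                        }
                    )
        zone_tables[stage] = claw_mod.zone_transition_table(stage_seqs, cm.zones_)

    pd.concat(behavior_frames, ignore_index=True).to_csv(
        out / "behavior.csv", index=False
    )
    pd.DataFrame(class_rows).to_csv(out / "trajectory_classes.csv", index=False)
    outputs += ["behavior.csv", "trajectory_classes.csv"]

    changes = {}
    stages = cfg["stages"]
    for prev, new in zip(stages[:-1], stages[1:]):
        rep = claw_mod.compare_claws(zone_tables[prev], zone_tables[new])
        changes[f"{prev}->{new}"] = rep.to_dict(orient="records")
    (out / "claw_changes.json").write_text(json.dumps(changes, indent=2, default=str))
    outputs.append("claw_changes.json")

    # ---- dynamic DDM on the canonical deliberative->committed path -------
    log.info("dynamic DDM fitting")
    traj = cfg["ddm"]["trajectory"]
    dyn_report = _dynamic_ddm_report(cm, cca, pre_trials, traj, cfg["ddm"]["n_sim"], seed)
    (out / "ddm_dynamic.json").write_text(json.dumps(dyn_report, indent=2, default=str))
    outputs.append("ddm_dynamic.json")

    # ---- learning-effect statistics ---------------------------------------
    log.info("learning-effect statistics")
    table = pd.DataFrame(engagement_rows)
    try:
        model = stats_mod.LearningEffectModel().fit(table)
        if model.report_.significant:
            model.pointwise()
        rep = model.report_
        stats_out = {
            "selected_model": rep.selected_model,
            "omnibus_pvalues": rep.omnibus_pvalues,
            "omnibus_alpha": rep.omnibus_alpha,
            "significant": rep.significant,
            "windows": rep.windows,
        }
    except Exception as exc:  # degenerate tables on tiny runs
        stats_out = {"error": str(exc)}
    (out / "learning_effect.json").write_text(json.dumps(stats_out, indent=2))
    outputs.append("learning_effect.json")

    io_mod.config_to_yaml(base, out / "network_config.yaml")
    outputs.append("network_config.yaml")
    io_mod.write_manifest(out, seed, cfg, outputs)
    return out


def _match_path(path: list[str], target: list[str]) -> bool:
    """True when the trial belongs to the trajectory type ``target``: its
    zone path visits the target zones in order, ends in the final target
    zone, and never enters a committed/reversal zone outside the target."""
    core = [z for z in path if z not in ("other", "V")]
    collapsed = [z for i, z in enumerate(core) if i == 0 or core[i - 1] != z]
    if not collapsed or collapsed[-1] != target[-1]:
        return False
    banned = {"III", "IV", "VI"} - set(target)
    if any(z in banned for z in collapsed):
        return False
    it = iter(collapsed)
    return all(z in it for z in target)


def _dynamic_ddm_report(cm, cca, trials, traj, n_sim, seed):
    paths = cm.transform(trials)
    matched = [t for t, p in zip(trials, paths) if _match_path(p, traj)]
    if len(matched) < 50:
        return {"error": f"only {len(matched)} trials follow {'->'.join(traj)}"}
    fit = ddm_mod.fit_static(
        [t.choice for t in matched],
        np.array([t.decision_time for t in matched]) / 1000.0,
        np.array([t.consolidation_time for t in matched]) / 1000.0,
        include_consolidation=True,
    )
    dwell, summaries = _zone_dwells_and_summaries(cm, matched, traj)
    b_pct, v_pct = ddm_mod.derive_percent_changes(summaries, cca, fit)
    schedule = ddm_mod.PhaseSchedule(
        zones=list(traj), dwell_ms=dwell, boundary_pct=b_pct, drift_pct=v_pct
    )
    params = ddm_mod.solve_phase_params(schedule, fit)
    rts = np.array([t.decision_time + t.consolidation_time for t in matched]) / 1000.0
    comparison = ddm_mod.compare_models(
        fit, params, schedule, [t.choice for t in matched], rts,
        n_sim=n_sim, seed=seed + 1,
    )
    p = fit.params
    return {
        "trajectory": "->".join(traj),
        "n_trials": len(matched),
        "static": {"a": p.a, "v": p.v, "tr": p.tr, "z": p.z,
                   "loglike": fit.loglike},
        "schedule": {"dwell_ms": dwell, "boundary_pct": b_pct, "drift_pct": v_pct},
        "dynamic": {"a": params.a, "v": params.v},
        "comparison": comparison,
    }


def _zone_dwells_and_summaries(cm, trials, traj):
    """Mean dwell (ms) and mean activity summary per zone along a path."""
    from . import ensembles as E

    dwell = {z: [] for z in traj}
    sums: dict[str, list] = {z: [] for z in traj}
    for t in trials:
        seq = cm._trial_sequence(t)
        binned = claw_mod.bin_rates(t.decision_rates, cm.bin_width_ms, t.dt_ms)
        # map each decision bin to its zone (skip the prepended baseline bin)
        expanded = seq.expand()[1:]
        for b in range(min(len(expanded), binned.shape[0])):
            z = cm.zones_.get(int(expanded[b]), "other")
            if z in sums:
                sums[z].append(E.summarize_activity(binned[b][None, :]))
        for z in traj:
            n = int(np.sum([cm.zones_.get(int(s), "other") == z for s in expanded]))
            if n:
                dwell[z].append(n * cm.bin_width_ms)
    dwell_ms = [float(np.mean(dwell[z])) if dwell[z] else cm.bin_width_ms for z in traj]
    summaries = [np.mean(sums[z], axis=0) for z in traj]
    return dwell_ms, summaries
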