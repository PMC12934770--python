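"""Tidy-CSV, YAML and manifest I/O.

Rates travel as one row per (trial, time bin, cell type, channel) with
``t_ms`` measured from cue onset (negative during the baseline segment);
behaviour as one row per trial.  Network configuration round-trips through
YAML with type-level weight keys written ``"pre->post"``.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParameterError
from .synth import NetworkConfig, STREAMS, TrialRecord, stream_index


def rates_to_frame(
    trials: list[TrialRecord], bin_width_ms: float = 10.0
) -> pd.DataFrame:
    """Tidy long table of (binned) firing rates for a list of trials.

    The ``trial`` column is the position in the list, which keeps the key
    unique even when records from several sessions are pooled.
    """
    from .claw import bin_rates

    frames = []
    for row_id, t in enumerate(trials):
        per_bin = int(round(bin_width_ms / t.dt_ms))
        # align bin edges to cue onset
        offset = t.onset_index % per_bin
        binned = bin_rates(t.rates[offset:], bin_width_ms, t.dt_ms)
        n_pre = (t.onset_index - offset) // per_bin
        t_ms = (np.arange(binned.shape[0]) - n_pre) * bin_width_ms
        for j, s in enumerate(STREAMS):
            frames.append(
                pd.DataFrame(
                    {
                        "trial": row_id,
                        "stage": t.learning_stage,
                        "t_ms": t_ms,
                        "cell_type": s.cell_type,
                        "channel": s.channel,
                        "rate_hz": binned[:, j],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def behavior_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """One row per trial; the ``trial`` column is the list position."""
    return pd.DataFrame(
        {
            "trial": list(range(len(trials))),
            "stage": [t.learning_stage for t in trials],
            "block": [t.block for t in trials],
            "choice": [t.choice for t in trials],
            "decision_time_ms": [t.decision_time for t in trials],
            "consolidation_ms": [t.consolidation_time for t in trials],
        }
    )


def frames_to_trials(
    rates: pd.DataFrame, behavior: pd.DataFrame
) -> list[TrialRecord]:
    """Rebuild trial records from the tidy tables (at the stored bin grid)."""
    required = {"trial", "stage", "t_ms", "cell_type", "channel", "rate_hz"}
    if not required <= set(rates.columns):
        raise ParameterError(f"rates table lacks {sorted(required - set(rates.columns))}")
    trials = []
    beh = behavior.set_index("trial")
    for trial_id, g in rates.groupby("trial"):
        t_vals = np.sort(g["t_ms"].unique())
        dt = float(t_vals[1] - t_vals[0]) if len(t_vals) > 1 else 10.0
        mat = np.zeros((len(t_vals), len(STREAMS)))
        pos = {t: i for i, t in enumerate(t_vals)}
        for (ct, ch), sub in g.groupby(["cell_type", "channel"]):
            j = stream_index(ct if ch == "shared" else f"{ct}-{ch}")
            mat[[pos[t] for t in sub["t_ms"]], j] = sub["rate_hz"].to_numpy()
        b = beh.loc[trial_id]
        trials.append(
            TrialRecord(
                trial_index=int(trial_id),
                rates=mat,
                choice=str(b["choice"]),
                decision_time=float(b["decision_time_ms"]),
                consolidation_time=float(b["consolidation_ms"]),
                learning_stage=int(b["stage"]),
                onset_index=int(np.searchsorted(t_vals, 0)),
                dt_ms=dt,
                block=str(b.get("block", "")),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# configuration


def config_to_yaml(config: NetworkConfig, path: str | Path) -> None:
    d = asdict(config)
    d["weights"] = {f"{a}->{b}": w for (a, b), w in config.weights.items()}
    d["w_dspn_bounds"] = list(config.w_dspn_bounds)
    d["w_ispn_bounds"] = list(config.w_ispn_bounds)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_from_yaml(path: str | Path) -> NetworkConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["weights"] = {
        tuple(k.split("->")): float(w) for k, w in d["weights"].items()
    }
    d["w_dspn_bounds"] = tuple(d["w_dspn_bounds"])
    d["w_ispn_bounds"] = tuple(d["w_ispn_bounds"])
    return NetworkConfig(**d)


# ---------------------------------------------------------------------------
# manifest


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, seed: int, settings: dict, outputs: list[str]
) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "package": "cbgtclaw",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "settings": settings,
        "outputs": {
            name: file_sha256(out_dir / name)
            for name in outputs
            if (out_dir / name).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
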