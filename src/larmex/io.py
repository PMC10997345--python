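"""File formats: EMA tables as CSV, configs as YAML, reports as JSON.

The single public data format is a long-format CSV with header
``day,occasion,m1..mk,e,observed`` — one row per prompt.  Simulated datasets
can carry a ground-truth sidecar CSV (``<stem>.truth.csv``) holding each
day's realized random effects in the canonical flattening order plus the
stability flag.  Every CLI run writes a provenance JSON (config echo, seed,
package version) next to its outputs so any file can be regenerated.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import model as _model
from .evaluate import network_param_names
from .model import DayDraw, ModelSpec, spec_from_dict, spec_to_dict
from .simulate import EmaDataset, SimConfig

__all__ = ["write_ema_csv", "read_ema_csv", "load_config", "sim_config_from_dict",
           "default_model_config", "write_provenance", "write_fit_report"]

_MOOD_RE = re.compile(r"^m(\d+)$")


def write_ema_csv(data: EmaDataset, path: str | Path, ground_truth: bool = True) -> Path:
    """Write the EMA table; the truth sidecar is written when available."""
    path = Path(path)
    data.df.to_csv(path, index=False)
    if ground_truth and data.draws is not None:
        names = network_param_names(data.k)
        rows = [{"day": d.day_index, **dict(zip(names, d.b)), "stable": d.stable}
                for d in data.draws]
        pd.DataFrame(rows).to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_ema_csv(path: str | Path) -> EmaDataset:
    """Read an EMA CSV, inferring k from the ``m<j>`` columns."""
    path = Path(path)
    df = pd.read_csv(path)
    moods = sorted((int(m.group(1)), c) for c in df.columns
                   if (m := _MOOD_RE.match(c)))
    if not moods:
        raise ValueError(f"{path}: no mood columns (m1, m2, ...) found")
    k = len(moods)
    if [j for j, _ in moods] != list(range(1, k + 1)):
        raise ValueError(f"{path}: mood columns must be m1..m{k} without gaps")
    for col in ("day", "occasion", "e"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "observed" not in df.columns:
        df["observed"] = True
    df["observed"] = df["observed"].astype(bool)
    draws = None
    sidecar = path.with_suffix(".truth.csv")
    if sidecar.exists():
        truth = pd.read_csv(sidecar)
        names = network_param_names(k)
        draws = [DayDraw.from_vector(int(r["day"]), r[names].to_numpy(dtype=float),
                                     k, stable=bool(r.get("stable", True)))
                 for _, r in truth.iterrows()]
    return EmaDataset(df=df, k=k, draws=draws)


_SIM_KEYS = {"n_days", "n_per_day", "candidate_pool", "init_range", "exo_range",
             "missing_rate", "seed", "exo_per_day"}


def sim_config_from_dict(d: Mapping, spec: ModelSpec) -> SimConfig:
    unknown = set(d) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("init_range", "exo_range"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    return SimConfig(spec=spec, **kwargs)


_TOP_KEYS = {"model", "simulation", "fit", "recover"}


def load_config(path: str | Path) -> dict:
    """Load a YAML run config; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown top-level config keys {sorted(unknown)}")
    return dict(cfg)


def default_model_config() -> dict:
    """Config dict for the reference two-mood network."""
    return spec_to_dict(_model.reference_two_mood_spec())


def write_provenance(out_dir: str | Path, command: str, config: Mapping,
                     seed) -> Path:
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = {"command": command, "config": _jsonable(config), "seed": seed,
            "larmex_version": __version__}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(blob, indent=2, sort_keys=True) + "\n")
    return path


def write_fit_report(result, path: str | Path, warnings_list=()) -> Path:
    path = Path(path)
    report = result.to_dict()
    report["warnings"] = list(warnings_list)
    path.write_text(json.dumps(report, indent=2) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
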