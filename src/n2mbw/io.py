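"""Readers/writers for the repo's open text formats.

* Trace: TSV with header ``t_s  flow_ml_s  fo2  fco2``, one row per sample,
  values at 6 significant digits; the sampling rate and free-form metadata
  live in a YAML sidecar (same stem, ``.meta.yaml``).  Write->read->write
  round-trips are byte-identical.
* SettingsProfile: flat YAML, one documented key per field, keys in the
  declared field order (byte-stable).
* Perturbation grid: JSON list of {id, group, edits} records.
* Cohort manifest: CSV (subject id, group, seed, file paths).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .domain import (Edit, Perturbation, SettingsProfile, SignalTrace,
                     BreathRecord, OutcomeSet)

TRACE_HEADER = "t_s\tflow_ml_s\tfo2\tfco2"


def write_trace(path: str | Path, trace: SignalTrace) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(TRACE_HEADER + "\n")
        for t, fl, o2, co2 in zip(trace.time, trace.flow, trace.fo2, trace.fco2):
            fh.write(f"{t:.6g}\t{fl:.6g}\t{o2:.6g}\t{co2:.6g}\n")
    sidecar = {"sample_rate": float(trace.sample_rate),
               "meta": _plain(trace.meta)}
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_trace(path: str | Path) -> SignalTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(path.suffix + ".meta.yaml")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = yaml.safe_load(fh)
        sample_rate = float(sidecar["sample_rate"])
        meta = sidecar.get("meta", {}) or {}
    else:
        dt = float(np.median(np.diff(df["t_s"].to_numpy())))
        sample_rate = 1.0 / dt
        meta = {}
    n = len(df)
    # rebuild an exactly uniform time base (TSV stores 6 significant digits)
    time = np.arange(n) / sample_rate + float(df["t_s"].iloc[0])
    return SignalTrace(sample_rate=sample_rate, time=time,
                       flow=df["flow_ml_s"].to_numpy(),
                       fo2=df["fo2"].to_numpy(), fco2=df["fco2"].to_numpy(),
                       meta=meta)


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays for YAML/JSON dumping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_settings(path: str | Path, profile: SettingsProfile) -> None:
    lines = []
    for f in dataclasses.fields(SettingsProfile):
        val = getattr(profile, f.name)
        if isinstance(val, tuple):
            val = list(val)
        # one key per line, declared field order (byte-stable round-trips)
        lines.append(yaml.safe_dump({f.name: val}, default_flow_style=False,
                                    sort_keys=False).rstrip())
    Path(path).write_text("\n".join(lines) + "\n")


def read_settings(path: str | Path) -> SettingsProfile:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "siii_window" in data:
        data["siii_window"] = tuple(data["siii_window"])
    return SettingsProfile(**data)


def write_grid(path: str | Path, grid: Iterable[Perturbation]) -> None:
    Path(path).write_text(
        json.dumps([p.as_dict() for p in grid], indent=1) + "\n")


def read_grid(path: str | Path) -> list[Perturbation]:
    data = json.loads(Path(path).read_text())
    return [Perturbation(id=rec["id"], group=rec["group"],
                         edits=tuple(Edit(e["field"], e["op"],
                                          _edit_value(e["value"]))
                                     for e in rec["edits"]))
            for rec in data]


def _edit_value(v: Any) -> Any:
    if isinstance(v, dict):  # add_by_set maps ds_set -> delta
        return {int(k): val for k, val in v.items()}
    if isinstance(v, list):
        return tuple(v)
    return v


def breath_table(breaths: list[BreathRecord]) -> pd.DataFrame:
    cols = ["index", "insp_start", "insp_end", "exp_end", "vt_insp_mL",
            "vt_exp_mL", "exp_n2_volume_mL", "reinsp_n2_volume_mL",
            "et_n2", "et_co2"]
    return pd.DataFrame([{c: getattr(b, c) for c in cols} for b in breaths])


def outcome_row(outcome: OutcomeSet, **extra: Any) -> dict[str, Any]:
    row = {"frc_mL": outcome.frc_mL, "lci": outcome.lci,
           "cev_mL": outcome.cev_mL,
           "n_washout_breaths": outcome.n_washout_breaths,
           "scond": outcome.scond, "sacin": outcome.sacin,
           "scond_vt": outcome.scond_vt, "sacin_vt": outcome.sacin_vt,
           "spike_metric": outcome.spike_metric,
           "divot_metric": outcome.divot_metric}
    row.update(extra)
    return row
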