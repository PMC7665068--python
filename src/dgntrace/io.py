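"""Reading and writing traces, datasets and reports.

Traces travel as CSV with a ``frame,intensity[,state]`` header (0-based
frames), either one file per trace or long format with a ``trace_id``
column; dataset manifests are YAML.  Raw (unnormalized) intensity units are
used on disk; normalization is an in-memory concern of the model.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .sim import (DEFAULT_FRAME_INTERVAL, LabeledDataset, NoiseModel,
                  StatePath, Trace, TraceRecord)

__all__ = [
    "read_traces",
    "write_traces",
    "write_dataset",
    "read_dataset",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _parse_frame(df: pd.DataFrame, path, frame_interval: float):
    if not {"frame", "intensity"}.issubset(df.columns):
        raise ValueError(f"{path}: header must contain frame,intensity")
    try:
        intens = df["intensity"].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric intensity cell: {exc}") from exc
    order = np.argsort(df["frame"].astype(int).to_numpy(), kind="stable")
    return Trace(intens[order], frame_interval=frame_interval)


def read_traces(path, frame_interval: float = DEFAULT_FRAME_INTERVAL
                ) -> list[Trace]:
    """Read traces from a CSV file (single-trace or long format).

    Raises a parse error (ValueError) with the offending file/cell for
    malformed input; an empty file is an error, not an empty list.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty trace file") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if "trace_id" in df.columns:
        out = []
        for tid, g in df.groupby("trace_id", sort=True):
            tr = _parse_frame(g, path, frame_interval)
            tr.metadata["trace_id"] = tid
            out.append(tr)
        return out
    return [_parse_frame(df, path, frame_interval)]


def write_traces(traces: Sequence[Trace], path,
                 paths: Sequence[StatePath] | None = None) -> None:
    """Write traces (and optional state paths) as long-format CSV."""
    rows = []
    for i, tr in enumerate(traces):
        tid = tr.metadata.get("trace_id", i)
        for f in range(len(tr)):
            row = {"trace_id": tid, "frame": f,
                   "intensity": tr.intensities[f]}
            if paths is not None and paths[i] is not None:
                row["state"] = int(paths[i].states[f])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dataset(dataset: LabeledDataset, directory) -> Path:
    """Write a dataset as long-format CSV plus a YAML manifest.

    Returns the manifest path.  The manifest records the mode, state
    cardinality, noise parameters, seed, achieved aSNR and per-record split
    tags, so the dataset can be reloaded bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "traces.csv"
    write_traces([r.trace for r in dataset.records], csv_path,
                 [r.path for r in dataset.records])
    manifest = {
        "mode": dataset.mode,
        "s_max": int(dataset.s_max),
        "frame_interval": float(dataset.records[0].trace.frame_interval),
        "achieved_asnr": None if dataset.achieved_asnr is None
        else float(dataset.achieved_asnr),
        "seed": dataset.seed,
        "noise": None if dataset.noise is None else {
            "unit_intensity": dataset.noise.unit_intensity,
            "gaussian_sd": dataset.noise.gaussian_sd,
            "shot_noise": dataset.noise.shot_noise,
            "blink_rate": dataset.noise.blink_rate,
            "blink_mean_duration": dataset.noise.blink_mean_duration,
        },
        "splits": [r.split for r in dataset.records],
        "labeled": [r.path is not None for r in dataset.records],
        "traces_csv": csv_path.name,
    }
    manifest["config_hash"] = config_hash(manifest)
    man_path = directory / "manifest.yaml"
    with open(man_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return man_path


def read_dataset(manifest_path) -> LabeledDataset:
    """Reload a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    fi = man["frame_interval"]
    df = pd.read_csv(manifest_path.parent / man["traces_csv"])
    records = []
    for i, (tid, g) in enumerate(df.groupby("trace_id", sort=True)):
        tr = _parse_frame(g, manifest_path, fi)
        tr.metadata["trace_id"] = tid
        sp = None
        if man["labeled"][i] and "state" in g.columns:
            sp = StatePath(g["state"].to_numpy(dtype=int), man["s_max"], fi)
        records.append(TraceRecord(tr, sp, man["splits"][i]))
    noise = None if man["noise"] is None else NoiseModel(**man["noise"])
    return LabeledDataset(records, man["mode"], man["s_max"],
                          man["achieved_asnr"], noise, man["seed"])
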