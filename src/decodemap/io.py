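"""File formats: HDF5 epoch containers, CSV map/table exports, manifests.

The epoch container is a self-describing HDF5 file:

* ``trials``  — (n, p) float64
* ``labels``  — (n,) int8 in {-1, +1}
* ``layout/`` — optional group: ``channel_positions_cm`` (n_channels, 3),
  attrs ``sampling_rate_hz``, ``n_channels``, ``n_times``
* root attrs  — ``schema_version`` ("1.0"), ``feature_order``
  ("channel_major"), ``config`` (JSON string of provenance)

CSV exports use a fixed dialect (comma, UTF-8, header row, '.' decimal,
numerics at 6 significant digits) so re-saving identical results yields
byte-identical files.
"""

from __future__ import annotations

import json
import hashlib
import platform
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .decoding import EpochedDataset, FittedDecoder, SensorLayout, Standardizer
from .maps import MultivariateBrainMap
from .selection import ModelSelectionTable

__all__ = [
    "SCHEMA_VERSION",
    "save_epochs",
    "load_epochs",
    "save_decoder",
    "load_decoder",
    "map_to_csv",
    "map_to_long_csv",
    "save_outputs",
    "write_manifest",
]

SCHEMA_VERSION = "1.0"
FLOAT_FMT = "%.6g"


def save_epochs(data: EpochedDataset, path) -> None:
    """Write an EpochedDataset to the HDF5 epoch container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=data.trials, dtype="f8")
        f.create_dataset("labels", data=data.labels, dtype="i1")
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["feature_order"] = "channel_major"
        f.attrs["config"] = json.dumps(data.meta, default=str, sort_keys=True)
        if data.layout is not None:
            g = f.create_group("layout")
            g.attrs["n_channels"] = data.layout.n_channels
            g.attrs["n_times"] = data.layout.n_times
            g.attrs["sampling_rate_hz"] = data.layout.sampling_rate_hz
            if data.layout.channel_positions_cm is not None:
                g.create_dataset(
                    "channel_positions_cm",
                    data=data.layout.channel_positions_cm,
                    dtype="f8",
                )


def load_epochs(path) -> EpochedDataset:
    """Load and validate an epoch container.

    Raises a descriptive error naming the violated invariant: wrong label
    alphabet (with a remap hint), inconsistent layout, or an unknown major
    schema version.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = str(f.attrs.get("schema_version", "0"))
        if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise ValueError(
                f"unsupported epoch-container schema version {version!r} "
                f"(this reader handles major version "
                f"{SCHEMA_VERSION.split('.')[0]})"
            )
        trials = np.asarray(f["trials"], dtype=float)
        labels = np.asarray(f["labels"])
        layout = None
        if "layout" in f:
            g = f["layout"]
            pos = (
                np.asarray(g["channel_positions_cm"], float)
                if "channel_positions_cm" in g
                else None
            )
            layout = SensorLayout(
                n_channels=int(g.attrs["n_channels"]),
                n_times=int(g.attrs["n_times"]),
                sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                channel_positions_cm=pos,
            )
        meta = json.loads(f.attrs.get("config", "{}"))
    if not np.all(np.isin(labels, (-1, 1))):
        bad = sorted(set(np.unique(labels)) - {-1, 1})
        raise ValueError(
            f"labels must be -1/+1 but file contains {bad}; remap them "
            "(e.g. {0,1} -> {-1,+1}) before saving"
        )
    return EpochedDataset(trials, labels, layout=layout, meta=meta)


def save_decoder(decoder: FittedDecoder, path, group: str = "decoder") -> None:
    """Serialize a fitted decoder to a single HDF5 group."""
    with h5py.File(Path(path), "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("raw_weights", data=decoder.raw_weights, dtype="f8")
        g.create_dataset("std_weights", data=decoder.std_weights, dtype="f8")
        g.create_dataset("std_mean", data=decoder.standardizer.mean, dtype="f8")
        g.create_dataset("std_sd", data=decoder.standardizer.sd, dtype="f8")
        g.attrs["intercept"] = decoder.intercept
        g.attrs["lambda"] = decoder.lam
        g.attrs["solver_report"] = json.dumps(
            decoder.solver_report, default=str, sort_keys=True
        )


def load_decoder(path, group: str = "decoder") -> FittedDecoder:
    with h5py.File(Path(path), "r") as f:
        g = f[group]
        mean = np.asarray(g["std_mean"], float)
        sd = np.asarray(g["std_sd"], float)
        return FittedDecoder(
            raw_weights=np.asarray(g["raw_weights"], float),
            intercept=float(g.attrs["intercept"]),
            lam=float(g.attrs["lambda"]),
            standardizer=Standardizer(
                mean=mean, sd=sd, constant_mask=np.zeros(mean.size, bool)
            ),
            std_weights=np.asarray(g["std_weights"], float),
            solver_report=json.loads(g.attrs["solver_report"]),
        )


def _weights_of(map_or_vec) -> np.ndarray:
    if isinstance(map_or_vec, MultivariateBrainMap):
        return map_or_vec.weights
    return np.asarray(map_or_vec, float)


def map_to_csv(map_or_vec, path, layout: Optional[SensorLayout] = None) -> None:
    """One weight per feature, with channel/time indices when structured."""
    w = _weights_of(map_or_vec)
    if layout is not None and layout.p == w.size:
        chan = np.repeat(np.arange(layout.n_channels), layout.n_times)
        time_ms = np.tile(layout.times_ms(), layout.n_channels)
        df = pd.DataFrame(
            {"feature": np.arange(w.size), "channel": chan,
             "time_ms": time_ms, "weight": w}
        )
    else:
        df = pd.DataFrame({"feature": np.arange(w.size), "weight": w})
    df.to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def map_to_long_csv(map_or_vec, layout: SensorLayout, path) -> None:
    """Long-format (channel, time_ms, weight) export of a structured map."""
    w = _weights_of(map_or_vec)
    if layout.p != w.size:
        raise ValueError("map length does not match the layout")
    grid = w.reshape(layout.n_channels, layout.n_times)
    rows = pd.DataFrame(
        {
            "channel": np.repeat(np.arange(layout.n_channels), layout.n_times),
            "time_ms": np.tile(layout.times_ms(), layout.n_channels),
            "weight": grid.ravel(),
        }
    )
    rows.to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def save_outputs(
    table: ModelSelectionTable,
    out_dir,
    *,
    layout: Optional[SensorLayout] = None,
    manifest_extra: Optional[dict] = None,
) -> dict:
    """Write the model-selection table, per-lambda maps and a manifest.

    Returns a dict of the file paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    table_path = out / "selection_table.csv"
    table.to_dataframe().to_csv(table_path, index=False, float_format=FLOAT_FMT)
    written["table"] = str(table_path)

    for row in table.rows:
        if row.ensemble is None:
            continue
        from .maps import main_map

        mp = main_map(row.ensemble)
        map_path = out / f"mbm_lambda_{row.lam:g}.csv"
        map_to_csv(mp, map_path, layout=layout)
        written[f"map_{row.lam:g}"] = str(map_path)

    manifest = {
        "config": table.config,
        "chosen_lambda": table.chosen_lambda,
        "admissible": table.admissible,
        "advisory_lambda": table.advisory_lambda,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = write_manifest(manifest, out / "manifest.json",
                                   hash_files=list(written.values()))
    written["manifest"] = str(manifest_path)
    return written


def write_manifest(payload: dict, path, hash_files=()) -> Path:
    """Write a JSON run manifest with tool version and artifact hashes."""
    from . import __version__

    path = Path(path)
    record = dict(payload)
    record.setdefault("tool", "decodemap")
    record.setdefault("tool_version", __version__)
    record.setdefault("python", platform.python_version())
    hashes = {}
    for fp in hash_files:
        fp = Path(fp)
        hashes[fp.name] = hashlib.sha256(fp.read_bytes()).hexdigest()
    if hashes:
        record["artifact_sha256"] = hashes
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
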