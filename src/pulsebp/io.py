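"""Record persistence: HDF5 groups and CSV + JSON-sidecar round trips."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .records import PPGRecord


def save_record_h5(rec: PPGRecord, path: str | Path, group: str | None = None) -> None:
    """Write a record as an HDF5 group (datasets samples/abp, attrs fs, id)."""
    path = Path(path)
    with h5py.File(path, "a") as f:
        g = f.require_group(group or rec.record_id or "record")
        for key in ("samples", "abp"):
            if key in g:
                del g[key]
        g.create_dataset("samples", data=rec.samples)
        if rec.abp is not None:
            g.create_dataset("abp", data=rec.abp)
        g.attrs["fs"] = rec.fs
        g.attrs["record_id"] = rec.record_id
        g.attrs["meta_json"] = json.dumps(rec.meta, default=str)


def load_record_h5(path: str | Path, group: str | None = None) -> PPGRecord:
    with h5py.File(path, "r") as f:
        if group is None:
            group = next(iter(f.keys()))
        g = f[group]
        meta = json.loads(g.attrs.get("meta_json", "{}"))
        return PPGRecord(
            samples=g["samples"][...],
            fs=float(g.attrs["fs"]),
            abp=g["abp"][...] if "abp" in g else None,
            record_id=str(g.attrs.get("record_id", group)),
            meta=meta,
        )


def list_records_h5(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as f:
        return list(f.keys())


def save_record_csv(rec: PPGRecord, path: str | Path) -> None:
    """Two-column (t_seconds, value) CSV with a .json metadata sidecar."""
    path = Path(path)
    t = np.arange(rec.samples.size) / rec.fs
    df = pd.DataFrame({"t_seconds": t, "value": rec.samples})
    if rec.abp is not None:
        df["abp"] = rec.abp
    df.to_csv(path, index=False)
    sidecar = {"fs": rec.fs, "record_id": rec.record_id, "meta": rec.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, default=str))


def load_record_csv(path: str | Path) -> PPGRecord:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        fs = float(sidecar["fs"])
        record_id = sidecar.get("record_id", path.stem)
        meta = sidecar.get("meta", {})
    else:
        dt = np.diff(df["t_seconds"].to_numpy())
        fs = 1.0 / float(np.median(dt))
        record_id, meta = path.stem, {}
    return PPGRecord(
        samples=df["value"].to_numpy(),
        fs=fs,
        abp=df["abp"].to_numpy() if "abp" in df.columns else None,
        record_id=record_id,
        meta=meta,
    )
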