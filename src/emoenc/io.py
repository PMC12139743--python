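"""File formats: BIDS-style TSVs, face-table CSVs, raw binary + JSON
sidecar, and result tables.

All tabular artifacts round-trip losslessly (write -> read == source).
Schemas are validated eagerly with errors naming the offending column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BlockSchedule, HFBEpochs, RecordingSession
from .errors import SchemaError

__all__ = [
    "write_events_tsv", "read_events_tsv",
    "write_channels_tsv", "read_channels_tsv",
    "write_face_table_csv", "read_face_table_csv",
    "write_raw_binary", "read_raw_binary",
    "write_hfb_epochs", "read_hfb_epochs",
    "write_encoding_results_tsv", "read_encoding_results_tsv",
    "write_json", "read_json",
]

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "block_index", "features_present"]
CHANNELS_COLUMNS = ["name", "region", "status"]


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")


def write_events_tsv(schedule: BlockSchedule, path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> BlockSchedule:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EVENTS_COLUMNS, f"events TSV {path}")
    return BlockSchedule.from_frame(df)


def write_channels_tsv(
    names, regions, path, bad: set[str] | None = None
) -> None:
    bad = bad or set()
    pd.DataFrame(
        {
            "name": list(names),
            "region": list(regions),
            "status": ["bad" if n in bad else "good" for n in names],
        }
    ).to_csv(path, sep="\t", index=False)


def read_channels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CHANNELS_COLUMNS, f"channels TSV {path}")
    bad_status = set(df["status"]) - {"good", "bad"}
    if bad_status:
        raise SchemaError(f"channels TSV {path}: unknown status {sorted(bad_status)}")
    return df


def write_face_table_csv(face_table: pd.DataFrame, feature_names, path) -> None:
    cols = ["time_s", "face_id", *feature_names]
    _require_columns(face_table, cols, "face table")
    face_table[cols].to_csv(path, index=False)


def read_face_table_csv(path, feature_names) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "face_id", *feature_names],
                     f"features CSV {path}")
    return df


def write_raw_binary(session: RecordingSession, out_dir, stem: str = "raw") -> None:
    """Float32 little-endian [n_channels x n_samples] (C order) plus a
    JSON sidecar carrying sampling metadata, and a channels TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.signal.astype("<f4").tofile(out / f"{stem}.bin")
    sidecar = {
        "fs": session.fs,
        "n_channels": session.n_channels,
        "n_samples": session.n_samples,
        "channel_names": session.channel_names,
        "dtype": "<f4",
        "order": "C",
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    write_channels_tsv(
        session.channel_names, session.channel_regions,
        out / f"{stem}_channels.tsv", bad=session.bad_channels,
    )


def read_raw_binary(in_dir, stem: str = "raw") -> RecordingSession:
    out = Path(in_dir)
    sidecar = json.loads((out / f"{stem}.json").read_text())
    for key in ("fs", "n_channels", "n_samples", "channel_names"):
        if key not in sidecar:
            raise SchemaError(f"raw sidecar {stem}.json: missing field {key!r}")
    sig = np.fromfile(out / f"{stem}.bin", dtype=sidecar.get("dtype", "<f4"))
    sig = sig.reshape(sidecar["n_channels"], sidecar["n_samples"]).astype(float)
    channels = read_channels_tsv(out / f"{stem}_channels.tsv")
    bad = set(channels.loc[channels["status"] == "bad", "name"])
    return RecordingSession(
        signal=sig,
        fs=float(sidecar["fs"]),
        channel_names=list(channels["name"]),
        channel_regions=list(channels["region"]),
        bad_channels=bad,
    )


def write_hfb_epochs(epochs: HFBEpochs, out_dir, stem: str = "hfb") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / f"{stem}.npz", amplitude=epochs.amplitude)
    meta = {
        "fs": epochs.fs,
        "channel_names": epochs.channel_names,
        "channel_regions": epochs.channel_regions,
    }
    (out / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    write_events_tsv(epochs.schedule, out / f"{stem}_events.tsv")


def read_hfb_epochs(in_dir, stem: str = "hfb") -> HFBEpochs:
    out = Path(in_dir)
    with np.load(out / f"{stem}.npz") as z:
        amplitude = z["amplitude"]
    meta = json.loads((out / f"{stem}.json").read_text())
    schedule = read_events_tsv(out / f"{stem}_events.tsv")
    return HFBEpochs(
        amplitude=amplitude,
        fs=float(meta["fs"]),
        schedule=schedule,
        channel_names=list(meta["channel_names"]),
        channel_regions=list(meta["channel_regions"]),
    )


def write_encoding_results_tsv(results, path) -> None:
    """One row per (participant, area, condition): mean r, per-fold r
    and the regularisation used."""
    rows = []
    for res in results:
        row = {
            "participant": res.participant,
            "area": res.area,
            "condition": res.condition,
            "mean_r": res.mean_r,
            "lambda": res.lambda_used,
        }
        for i, r in enumerate(res.fold_r):
            row[f"fold{i}_r"] = r
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_encoding_results_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["participant", "area", "condition", "mean_r", "lambda"],
                     f"encoding results TSV {path}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
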