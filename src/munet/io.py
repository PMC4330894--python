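"""Reading and writing the pipeline's on-disk artifacts.

Recordings live in one HDF5 file (group per subject with /data and an fs
attribute); everything else is CSV so artifacts stay human-inspectable.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EventTable, Recording, SensorArray

__all__ = [
    "save_layout", "load_layout", "save_cohort_meta", "load_cohort_meta",
    "save_events", "load_events", "save_recordings", "load_recordings",
    "save_matrix", "load_matrix",
]


def save_layout(arr: SensorArray, path: Path) -> None:
    pd.DataFrame({"sensor_id": arr.sensor_id,
                  "x_mm": arr.position[:, 0],
                  "y_mm": arr.position[:, 1],
                  "z_mm": arr.position[:, 2]}).to_csv(path, index=False)


def load_layout(path: Path) -> SensorArray:
    df = pd.read_csv(path)
    return SensorArray.from_positions(
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        sensor_id=df["sensor_id"].astype(str).tolist())


def save_cohort_meta(metas, path: Path) -> None:
    pd.DataFrame([{"subject_id": m.subject_id, "group": m.group,
                   "age": m.age, "impf": m.impf, "seed": m.seed}
                  for m in metas]).to_csv(path, index=False)


def load_cohort_meta(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "group": str})


def save_events(events_by_subject: dict[str, EventTable], path: Path) -> None:
    rows = []
    for sid, ev in events_by_subject.items():
        for onset, condition in zip(ev.onset, ev.condition):
            rows.append({"subject_id": sid, "onset_s": onset,
                         "condition": condition})
    pd.DataFrame(rows, columns=["subject_id", "onset_s", "condition"]
                 ).to_csv(path, index=False)


def load_events(path: Path) -> dict[str, EventTable]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    out = {}
    for sid, sub in df.groupby("subject_id"):
        out[sid] = EventTable(onset=sub["onset_s"].to_numpy(),
                              condition=sub["condition"].tolist())
    return out


def save_recordings(recordings: list[Recording], path: Path) -> None:
    with h5py.File(path, "w") as f:
        for rec in recordings:
            g = f.create_group(rec.subject_id)
            g.create_dataset("data", data=rec.data, compression="gzip")
            g.attrs["fs"] = rec.fs


def load_recordings(path: Path) -> dict[str, Recording]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            out[sid] = Recording(subject_id=sid, fs=float(f[sid].attrs["fs"]),
                                 data=f[sid]["data"][()])
    return out


def save_matrix(values: np.ndarray, channel_ids: list[str],
                path: Path) -> None:
    pd.DataFrame(values, index=channel_ids,
                 columns=channel_ids).to_csv(path)


def load_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
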