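"""Serialization: HDF5 dataset container, long-format CSV, map CSVs, CV tables.

The on-disk dataset container is a single HDF5 file holding the 4-D data
array plus a JSON sidecar (same path with a ``.json`` suffix appended)
carrying subject ids, labels, channel names, the time axis and the sampling
rate.  A long-format CSV (subject, trial, category, animacy, channel,
time_ms, value) is provided for interoperability with dataframe tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core_data import EpochedEEG
from .sensitivity import ScalpTimeMap
from .svm import CVResult

__all__ = [
    "save_dataset", "load_dataset",
    "to_long_csv", "from_long_csv",
    "save_map", "load_map",
    "cv_result_to_frame", "save_cv_result",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_dataset(d: EpochedEEG, path: str | Path) -> None:
    """Write the data array to HDF5 and the metadata to a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=d.data)
        f.create_dataset("category_labels", data=d.category_labels)
        f.create_dataset("animacy_labels", data=d.animacy_labels)
    meta = {
        "subject_ids": d.subject_ids,
        "channel_names": d.channel_names,
        "times_ms": d.times_ms.tolist(),
        "sampling_rate_hz": d.sampling_rate_hz,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_dataset(path: str | Path) -> EpochedEEG:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        category = f["category_labels"][()]
        animacy = f["animacy_labels"][()]
    meta = json.loads(_sidecar(path).read_text())
    return EpochedEEG(
        data=data,
        subject_ids=meta["subject_ids"],
        category_labels=category,
        animacy_labels=animacy,
        channel_names=meta["channel_names"],
        times_ms=np.asarray(meta["times_ms"]),
        sampling_rate_hz=meta["sampling_rate_hz"],
    )


def to_long_csv(d: EpochedEEG, path: str | Path) -> None:
    """Export to long format: one row per (subject, trial, channel, sample)."""
    n_s, n_tr, n_ch, n_t = d.data.shape
    frame = pd.DataFrame({
        "subject": np.repeat(d.subject_ids, n_tr * n_ch * n_t),
        "trial": np.tile(np.repeat(np.arange(n_tr), n_ch * n_t), n_s),
        "category": np.repeat(d.category_labels.reshape(-1), n_ch * n_t),
        "animacy": np.repeat(d.animacy_labels.reshape(-1), n_ch * n_t),
        "channel": np.tile(np.repeat(d.channel_names, n_t), n_s * n_tr),
        "time_ms": np.tile(d.times_ms, n_s * n_tr * n_ch),
        "value": d.data.reshape(-1),
    })
    frame.to_csv(path, index=False)


def from_long_csv(path: str | Path, sampling_rate_hz: float | None = None
                  ) -> EpochedEEG:
    """Rebuild a rectangular dataset from the long-format CSV."""
    frame = pd.read_csv(path)
    subjects = list(dict.fromkeys(frame["subject"]))
    channels = list(dict.fromkeys(frame["channel"]))
    times = np.sort(frame["time_ms"].unique())
    trials = np.sort(frame["trial"].unique())
    n_s, n_tr, n_ch, n_t = len(subjects), trials.size, len(channels), times.size

    frame = frame.sort_values(["subject", "trial", "channel", "time_ms"],
                              key=lambda col: (
                                  col.map({s: i for i, s in enumerate(subjects)})
                                  if col.name == "subject" else
                                  col.map({c: i for i, c in enumerate(channels)})
                                  if col.name == "channel" else col))
    data = frame["value"].to_numpy().reshape(n_s, n_tr, n_ch, n_t)
    per_trial = frame.iloc[:: n_ch * n_t]
    category = per_trial["category"].to_numpy().reshape(n_s, n_tr)
    animacy = per_trial["animacy"].to_numpy().reshape(n_s, n_tr)
    if sampling_rate_hz is None:
        sampling_rate_hz = 1000.0 / float(np.diff(times).mean())
    return EpochedEEG(
        data=data, subject_ids=subjects, category_labels=category,
        animacy_labels=animacy, channel_names=channels,
        times_ms=times.astype(float), sampling_rate_hz=sampling_rate_hz,
    )


def save_map(m: ScalpTimeMap, path: str | Path) -> None:
    """Map CSV: rows = channels, columns = times_ms; JSON sidecar with kind."""
    path = Path(path)
    frame = pd.DataFrame(m.values, index=m.channel_names,
                         columns=[f"{t:g}" for t in m.times_ms])
    frame.index.name = "channel"
    frame.to_csv(path)
    _sidecar(path).write_text(json.dumps({"map_kind": m.map_kind}))


def load_map(path: str | Path) -> ScalpTimeMap:
    path = Path(path)
    frame = pd.read_csv(path, index_col="channel")
    kind = "sensitivity"
    sidecar = _sidecar(path)
    if sidecar.exists():
        kind = json.loads(sidecar.read_text()).get("map_kind", kind)
    return ScalpTimeMap(
        values=frame.to_numpy(),
        channel_names=list(frame.index),
        times_ms=np.array([float(c) for c in frame.columns]),
        map_kind=kind,
    )


def cv_result_to_frame(cv: CVResult) -> pd.DataFrame:
    return pd.DataFrame({
        "subject": cv.subject_ids(),
        "accuracy": cv.accuracies,
        "c": [s.params.c for s in cv.subjects],
        "gamma": [s.params.gamma for s in cv.subjects],
        "p_perm": [s.p_value for s in cv.subjects],
    })


def save_cv_result(cv: CVResult, csv_path: str | Path,
                   json_path: str | Path | None = None) -> None:
    """CSV table of per-subject results plus a JSON summary."""
    cv_result_to_frame(cv).to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "scheme": cv.scheme,
            "train_unit": cv.train_unit,
            "test_unit": cv.test_unit,
            "biased": cv.biased,
            "mean_accuracy": cv.mean_accuracy,
            "notes": cv.notes,
        }
        Path(json_path).write_text(json.dumps(summary, indent=1, default=str))
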