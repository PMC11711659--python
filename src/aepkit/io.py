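"""Serialization: HDF5 session containers and delimited-text outputs.

Session container layout (one file per ear)::

    /                       attrs: params_json, metadata_json, seed
    /protocols/<name>/      attrs: sampling_rate
        channels/<ch>       1-D float64 voltage trace (µV)
        onsets_s            1-D float64 event onsets (s)
        events/<column>     per-event stimulus attributes

Averaged waveforms are written as tab-separated text with columns
``time_ms, mean_uv, sem_uv`` plus a JSON sidecar holding the condition
attributes and retained-epoch count.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import ContinuousRecording, EpochedAverage
from .simulate import EarSession, EarSimParams

__all__ = [
    "save_session",
    "load_session",
    "write_average",
    "read_average",
    "write_table",
]


def save_session(session: EarSession, path) -> Path:
    """Write one ear's session (all protocols) to an HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["params_json"] = json.dumps(dataclasses.asdict(session.params))
        f.attrs["metadata_json"] = json.dumps(session.metadata)
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        proto_grp = f.create_group("protocols")
        for name, rec in session.recordings.items():
            g = proto_grp.create_group(name)
            g.attrs["sampling_rate"] = rec.sampling_rate
            ch = g.create_group("channels")
            for cname, trace in rec.channels.items():
                ch.create_dataset(cname, data=np.asarray(trace, dtype=np.float64))
            g.create_dataset("onsets_s", data=rec.onsets_s)
            ev = g.create_group("events")
            for col in rec.event_attrs.columns:
                values = rec.event_attrs[col].to_numpy()
                if values.dtype.kind in ("U", "O"):
                    ev.create_dataset(
                        col, data=np.array([str(v) for v in values], dtype="S64")
                    )
                else:
                    ev.create_dataset(col, data=values)
    return path


def load_session(path) -> EarSession:
    """Read a session container written by :func:`save_session`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        params = EarSimParams(**json.loads(f.attrs["params_json"]))
        metadata = json.loads(f.attrs["metadata_json"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        recordings = {}
        for name, g in f["protocols"].items():
            channels = {
                cname: dset[()] for cname, dset in g["channels"].items()
            }
            columns = {}
            for col, dset in g["events"].items():
                values = dset[()]
                if values.dtype.kind == "S":
                    values = np.array([v.decode() for v in values])
                columns[col] = values
            recordings[name] = ContinuousRecording(
                channels=channels,
                sampling_rate=float(g.attrs["sampling_rate"]),
                onsets_s=g["onsets_s"][()],
                event_attrs=pd.DataFrame(columns),
            )
    return EarSession(params=params, metadata=metadata, recordings=recordings, seed=seed)


def write_average(avg: EpochedAverage, path) -> Path:
    """Averaged waveform as TSV plus a JSON sidecar of condition attrs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    avg.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "condition": avg.condition,
                "n_epochs_retained": avg.n_epochs_retained,
                "sem_defined": avg.sem_defined,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return path


def read_average(path) -> EpochedAverage:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EpochedAverage(
        time_ms=frame["time_ms"].to_numpy(),
        mean=frame["mean_uv"].to_numpy(),
        sem=frame["sem_uv"].to_numpy(),
        n_epochs_retained=int(meta.get("n_epochs_retained", 0)),
        condition=meta.get("condition", {}),
        sem_defined=bool(meta.get("sem_defined", True)),
    )


def write_table(frame: pd.DataFrame, path) -> Path:
    """Deterministic TSV output (fixed float formatting)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
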