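"""Readers and writers for the pipeline's on-disk formats.

Traces and sweeps go to CSV (``time_s,value``) or HDF5 (one group per
trial with the simulation configuration as attributes); spike trains and
event logs to JSON (times in seconds); operant event logs to CSV
(``event_type,time_s``); tracks to CSV (``t,x,y,z``); ground truth to
JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import Session, Track3D
from .core import Trace
from .synthkit import GroundTruth, SimConfig

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_traces_hdf5",
    "read_traces_hdf5",
    "write_spike_train_json",
    "read_spike_train_json",
    "write_session_csv",
    "read_session_csv",
    "write_track_csv",
    "read_track_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
]


def write_trace_csv(path, trace: Trace) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(path, index=False)


def read_trace_csv(path) -> Trace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace CSV needs at least two samples")
    dt = float(np.median(np.diff(t)))
    return Trace(t0=float(t[0]), dt=dt, values=df["value"].to_numpy())


def write_traces_hdf5(path, traces: list[Trace], cfg: SimConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        for i, tr in enumerate(traces):
            g = f.create_group(f"trial_{i:04d}")
            g.create_dataset("values", data=tr.values)
            g.attrs["t0"] = tr.t0
            g.attrs["dt"] = tr.dt
        if cfg is not None:
            for k, v in dataclasses.asdict(cfg).items():
                f.attrs[k] = v


def read_traces_hdf5(path) -> tuple[list[Trace], SimConfig | None]:
    with h5py.File(path, "r") as f:
        traces = [
            Trace(t0=float(g.attrs["t0"]), dt=float(g.attrs["dt"]), values=g["values"][()])
            for _, g in sorted(f.items())
        ]
        cfg = None
        if "seed" in f.attrs:
            fields = {fld.name for fld in dataclasses.fields(SimConfig)}
            kwargs = {k: v for k, v in f.attrs.items() if k in fields}
            kwargs["seed"] = int(kwargs["seed"])
            cfg = SimConfig(**kwargs)
    return traces, cfg


def write_spike_train_json(path, spike_times, unit_id: str = "", **meta) -> None:
    payload = {"unit_id": unit_id, "spike_times_s": np.asarray(spike_times).tolist(), **meta}
    Path(path).write_text(json.dumps(payload))


def read_spike_train_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["spike_times_s"] = np.asarray(payload["spike_times_s"], dtype=float)
    return payload


def write_session_csv(path, session: Session) -> None:
    rows = [("press", t) for t in session.press_times] + [
        ("reward", t) for t in session.reward_times
    ]
    rows.sort(key=lambda r: r[1])
    df = pd.DataFrame(rows, columns=["event_type", "time_s"])
    df.attrs["schedule"] = session.schedule
    with open(path, "w") as fh:
        fh.write(f"# schedule={session.schedule} duration={session.duration}\n")
        df.to_csv(fh, index=False)


def read_session_csv(path) -> Session:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    meta = dict(item.split("=") for item in header.lstrip("# ").split())
    presses = df.loc[df.event_type == "press", "time_s"].to_numpy()
    rewards = df.loc[df.event_type == "reward", "time_s"].to_numpy()
    return Session(
        press_times=presses,
        reward_times=rewards,
        schedule=meta["schedule"],
        duration=float(meta["duration"]),
    )


def write_track_csv(path, track: Track3D) -> None:
    pd.DataFrame({"t": track.t, "x": track.x, "y": track.y, "z": track.z}).to_csv(
        path, index=False
    )


def read_track_csv(path) -> Track3D:
    df = pd.read_csv(path)
    return Track3D(
        t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(), z=df["z"].to_numpy()
    )


def write_ground_truth_json(path, truth: GroundTruth) -> None:
    payload = {
        "true_event_times": truth.true_event_times.tolist(),
        "true_label": truth.true_label,
        "true_parameters": truth.true_parameters,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_event_times=np.asarray(payload["true_event_times"], dtype=float),
        true_label=payload["true_label"],
        true_parameters=payload["true_parameters"],
    )
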