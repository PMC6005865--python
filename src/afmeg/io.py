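"""Readers and writers for the pipeline's on-disk formats.

Event tables travel as CSV with a versioned comment header; epochs,
continuous recordings, sensor layouts and forward models live in HDF5
groups with a ``schema`` attribute; configurations are YAML mirroring the
dataclass field names; statistical results serialize to JSON.  Every
writer/reader pair is a round-trip identity on all fields, and readers
validate the schema field-by-field, naming what is missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .erf import EpochSet
from .synthgen import (ContinuousRecording, ForwardModel, SensorLayout,
                       SimulationConfig)

__all__ = [
    "write_events_csv", "read_events_csv",
    "write_epochs_h5", "read_epochs_h5",
    "write_recording_h5", "read_recording_h5",
    "write_forward_h5", "read_forward_h5",
    "save_simulation_config", "load_simulation_config",
    "write_json",
]

EVENTS_SCHEMA = "afmeg-events-v1"
REQUIRED_EVENT_COLUMNS = (
    "subject", "trial", "keystroke_index", "onset_ms", "pitch_played",
    "pitch_heard", "velocity", "seq_position", "position_class", "feedback",
    "is_error")


def write_events_csv(events: pd.DataFrame, path) -> None:
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {EVENTS_SCHEMA}\n")
        events.to_csv(fh, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed event table {path}: missing columns "
                         f"{missing}")
    return df


def _write_strings(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.asarray(values, dtype=object),
                         dtype=h5py.string_dtype())


def _read_strings(group: h5py.Group, name: str) -> np.ndarray:
    return group[name].asstr()[()]


def _check_schema(group: h5py.Group, expected: str) -> None:
    found = group.attrs.get("schema")
    if found != expected:
        raise ValueError(f"schema mismatch: expected {expected!r}, "
                         f"found {found!r}")


def _require(group: h5py.Group, names) -> None:
    missing = [n for n in names if n not in group]
    if missing:
        raise ValueError(f"HDF5 group {group.name!r} is missing fields "
                         f"{missing}")


# -- epochs -----------------------------------------------------------------

def write_epochs_h5(epochs: EpochSet, path, group: str = "epochs") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.attrs["schema"] = "afmeg-epochs-v1"
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("times", data=epochs.times)
        _write_strings(g, "conditions", epochs.conditions)
        _write_strings(g, "sensor_names", epochs.sensor_names)
        if epochs.subject is not None:
            g.attrs["subject"] = epochs.subject
        if epochs.covariates is not None:
            cov = g.create_group("covariates")
            for col in epochs.covariates.columns:
                vals = epochs.covariates[col].to_numpy()
                if vals.dtype == object:
                    _write_strings(cov, col, vals)
                else:
                    cov.create_dataset(col, data=vals)


def read_epochs_h5(path, group: str = "epochs") -> EpochSet:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        _check_schema(g, "afmeg-epochs-v1")
        _require(g, ["data", "times", "conditions"])
        cov = None
        if "covariates" in g:
            cols = {}
            for col in g["covariates"]:
                ds = g["covariates"][col]
                cols[col] = (ds.asstr()[()] if h5py.check_string_dtype(ds.dtype)
                             else ds[()])
            cov = pd.DataFrame(cols)
        return EpochSet(
            data=g["data"][()], times=g["times"][()],
            conditions=_read_strings(g, "conditions").astype(object),
            covariates=cov,
            subject=int(g.attrs["subject"]) if "subject" in g.attrs else None,
            sensor_names=list(_read_strings(g, "sensor_names")))


# -- layout -----------------------------------------------------------------

def _write_layout(g: h5py.Group, layout: SensorLayout) -> None:
    g.attrs["schema"] = "afmeg-layout-v1"
    g.attrs["threshold"] = layout.threshold
    g.create_dataset("positions", data=layout.positions)
    _write_strings(g, "pair_names", layout.pair_names)
    _write_strings(g, "sensor_names", layout.sensor_names)
    edges = np.argwhere(np.triu(layout.adjacency))
    g.create_dataset("adjacency_edges", data=edges)
    grp = g.create_group("groups")
    for name, idx in layout.groups.items():
        grp.create_dataset(name, data=np.asarray(idx, dtype=int))


def _read_layout(g: h5py.Group) -> SensorLayout:
    _check_schema(g, "afmeg-layout-v1")
    _require(g, ["positions", "pair_names", "sensor_names",
                 "adjacency_edges"])
    positions = g["positions"][()]
    n = positions.shape[0]
    adjacency = np.zeros((n, n), dtype=bool)
    edges = g["adjacency_edges"][()]
    if edges.size:
        adjacency[edges[:, 0], edges[:, 1]] = True
        adjacency |= adjacency.T
    groups = {name: g["groups"][name][()] for name in g.get("groups", [])}
    return SensorLayout(
        positions=positions,
        pair_names=list(_read_strings(g, "pair_names")),
        sensor_names=list(_read_strings(g, "sensor_names")),
        adjacency=adjacency, groups=groups,
        threshold=float(g.attrs.get("threshold", 0.0)))


def write_layout_h5(layout: SensorLayout, path, group: str = "layout") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        _write_layout(fh.create_group(group), layout)


def read_layout_h5(path, group: str = "layout") -> SensorLayout:
    with h5py.File(path, "r") as fh:
        return _read_layout(fh[group])


# -- continuous recordings --------------------------------------------------

def write_recording_h5(rec: ContinuousRecording, path,
                       group: str = "recording") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.attrs["schema"] = "afmeg-recording-v1"
        g.attrs["sfreq"] = rec.sfreq
        g.create_dataset("data", data=rec.data)
        g.create_dataset("triggers", data=rec.triggers)
        g.create_dataset("baseline_segments",
                         data=np.asarray(rec.baseline_segments, dtype=int))
        _write_strings(g, "sensor_names", rec.sensor_names)
        ev = g.create_group("events")
        for col in rec.events.columns:
            vals = rec.events[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                _write_strings(ev, col, vals.astype(str))
            else:
                ev.create_dataset(col, data=vals)


def read_recording_h5(path, group: str = "recording") -> ContinuousRecording:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        _check_schema(g, "afmeg-recording-v1")
        _require(g, ["data", "triggers", "baseline_segments", "events"])
        cols = {}
        for col in g["events"]:
            ds = g["events"][col]
            if h5py.check_string_dtype(ds.dtype):
                cols[col] = ds.asstr()[()].astype(object)
            else:
                cols[col] = ds[()]
        return ContinuousRecording(
            data=g["data"][()], sfreq=float(g.attrs["sfreq"]),
            triggers=g["triggers"][()],
            events=pd.DataFrame(cols),
            baseline_segments=[tuple(r) for r in g["baseline_segments"][()]],
            sensor_names=list(_read_strings(g, "sensor_names")))


# -- forward model ----------------------------------------------------------

def write_forward_h5(fm: ForwardModel, path, group: str = "forward") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.attrs["schema"] = "afmeg-forward-v1"
        g.create_dataset("leadfield", data=fm.leadfield)
        g.create_dataset("grid_coords", data=fm.grid_coords)
        _write_strings(g, "region_labels", fm.region_labels)
        _write_strings(g, "sensor_names", fm.sensor_names)


def read_forward_h5(path, group: str = "forward") -> ForwardModel:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        _check_schema(g, "afmeg-forward-v1")
        _require(g, ["leadfield", "grid_coords", "region_labels"])
        return ForwardModel(
            leadfield=g["leadfield"][()],
            grid_coords=g["grid_coords"][()],
            region_labels=_read_strings(g, "region_labels").astype(object),
            sensor_names=list(_read_strings(g, "sensor_names")))


# -- configs and results ----------------------------------------------------

def save_simulation_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
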