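"""Event storage: CSV/TSV with a commented metadata header, or HDF5.

The HDF5 layout keeps one group per (donor, condition) sample with one
dataset per event column and the store metadata as root attributes; the
CSV/TSV format carries the same metadata as ``# key = <json>`` comment
lines before the header row.  Metadata always records the schema version,
software version and column units, so gating can be re-run bit-identically
from a file alone.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .features import EVENT_COLUMNS

__all__ = ["EventStore", "write_events", "read_events", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_STRING_COLUMNS = ("donor_id", "condition_label")


@dataclass
class EventStore:
    """An event table plus the metadata needed to reproduce its gating."""

    events: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.metadata.setdefault("schema_version", SCHEMA_VERSION)
        self.metadata.setdefault("software_version", __version__)
        units = dict(EVENT_COLUMNS)
        units.update(self.metadata.get("column_units", {}))
        for col in self.events.columns:
            if col not in units:
                raise ValueError(
                    f"unknown event column {col!r}: declare its unit in "
                    "metadata['column_units']")
        self.metadata["column_units"] = {c: units[c] for c in self.events.columns}
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing and len(self.events):
            raise ValueError(f"event table is missing required column {missing[0]!r}")


def _format_of(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv"):
        return suffix[1:]
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r} (use csv, tsv or hdf5)")


def write_events(store: EventStore, path, format: str | None = None) -> None:
    """Write an event store; format inferred from the suffix unless given."""
    path = Path(path)
    fmt = _format_of(path, format)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path, "w") as fh:
            for key, value in store.metadata.items():
                fh.write(f"# {key} = {json.dumps(value)}\n")
            store.events.to_csv(fh, sep=sep, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            for key, value in store.metadata.items():
                fh.attrs[key] = json.dumps(value)
            if len(store.events) == 0:
                return
            keys = (store.events.groupby(["donor_id", "condition_label"], sort=True)
                    if {"donor_id", "condition_label"} <= set(store.events.columns)
                    else [(("all", "all"), store.events)])
            for (donor, condition), sample in keys:
                group = fh.create_group(f"{donor}/{condition.replace('/', '|')}")
                for col in sample.columns:
                    values = sample[col].to_numpy()
                    if col in _STRING_COLUMNS or values.dtype.kind in "OU":
                        group.create_dataset(
                            col, data=np.asarray(values, dtype=object),
                            dtype=h5py.string_dtype())
                    else:
                        group.create_dataset(col, data=np.asarray(values, dtype=float))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_events(path, format: str | None = None) -> EventStore:
    """Read an event store written by :func:`write_events`."""
    path = Path(path)
    fmt = _format_of(path, format)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        metadata: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, raw = line[1:].partition("=")
                metadata[key.strip()] = json.loads(raw)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            if line.strip():
                events = pd.read_csv(fh, sep=sep)
            else:
                events = pd.DataFrame(columns=list(EVENT_COLUMNS))
    elif fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            metadata = {key: json.loads(value) for key, value in fh.attrs.items()}
            frames = []
            for donor in fh:
                for condition in fh[donor]:
                    group = fh[donor][condition]
                    data = {}
                    for col in group:
                        values = group[col][()]
                        if values.dtype.kind in ("O", "S"):
                            values = np.array([v.decode() if isinstance(v, bytes) else v
                                               for v in values])
                        data[col] = values
                    frames.append(pd.DataFrame(data))
            events = (pd.concat(frames, ignore_index=True) if frames
                      else pd.DataFrame(columns=list(EVENT_COLUMNS)))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    declared = metadata.get("column_units", {})
    for col in events.columns:
        if col not in declared:
            raise ValueError(f"file metadata is missing units for column {col!r}")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing and len(events):
        raise ValueError(f"file is missing required column {missing[0]!r}")
    if len(events):
        events = events[[c for c in EVENT_COLUMNS if c in events.columns]
                        + [c for c in events.columns if c not in EVENT_COLUMNS]]
    return EventStore(events=events.reset_index(drop=True), metadata=metadata)
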