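"""Readers/writers for the persistent formats and the command log.

The canonical store is HDF5, mirroring the hierarchical folder structure
used for sweep data: ``/<prefix>/<channel>/sweep<k>`` datasets carrying the
sampling metadata as attributes, per-prefix set-membership tables, and an
append-only command log under ``/log``.  CSV import/export covers delimited
text exchange, and Axon Binary Format traces can be imported when the
optional ``pyabf`` dependency is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import h5py
import numpy as np
import pandas as pd

from .events import EventRecord
from .trace import ProvenanceNote, SweepSet, Trace


@dataclass
class CommandLogEntry:
    timestamp: str
    operation: str
    params: str
    outputs: str = ""

    @classmethod
    def now(cls, operation: str, params: str = "", outputs: str = ""):
        return cls(datetime.now(timezone.utc).isoformat(), operation, params,
                   outputs)


@dataclass
class DataFolderLayout:
    name: str = "nmFolder0"
    sweepsets: dict[tuple[str, str], SweepSet] = field(default_factory=dict)
    log: list[CommandLogEntry] = field(default_factory=list)

    def add(self, sweepset: SweepSet) -> None:
        self.sweepsets[(sweepset.prefix, sweepset.channel)] = sweepset


_REQUIRED_ATTRS = ("dt", "t_start", "units", "label")


def write_h5(layout: DataFolderLayout, path) -> str:
    path = str(path)
    with h5py.File(path, "w") as f:
        f.attrs["folder_name"] = layout.name
        for (prefix, channel), ss in layout.sweepsets.items():
            grp = f.require_group(f"{prefix}/{channel}")
            for k, tr in enumerate(ss):
                d = grp.create_dataset(f"sweep{k}", data=tr.samples)
                d.attrs["dt"] = tr.dt
                d.attrs["t_start"] = tr.t_start
                d.attrs["units"] = tr.units
                d.attrs["label"] = tr.label
                d.attrs["notes"] = json.dumps(
                    [[nt.timestamp, nt.operation, nt.params] for nt in tr.notes])
            sg = f.require_group(f"{prefix}/sets")
            for name, mem in ss.sets.items():
                if name in sg:
                    continue
                sg.create_dataset(name, data=np.asarray(mem, dtype=bool))
            if ss.groups:
                grp.attrs["groups"] = json.dumps(
                    {str(k): v for k, v in ss.groups.items()})
        log = f.create_dataset(
            "log", data=np.array([json.dumps([e.timestamp, e.operation,
                                              e.params, e.outputs])
                                  for e in layout.log],
                                 dtype=h5py.string_dtype()))
        log.attrs["append_only"] = True
    return path


def read_h5(path) -> DataFolderLayout:
    layout = DataFolderLayout()
    with h5py.File(str(path), "r") as f:
        layout.name = f.attrs.get("folder_name", "nmFolder0")
        for prefix, pgrp in f.items():
            if prefix == "log":
                continue
            sets_grp = pgrp.get("sets")
            for channel, cgrp in pgrp.items():
                if channel == "sets":
                    continue
                traces = []
                keys = sorted((k for k in cgrp if k.startswith("sweep")),
                              key=lambda s: int(s[5:]))
                for k in keys:
                    d = cgrp[k]
                    for a in _REQUIRED_ATTRS:
                        if a not in d.attrs:
                            raise ValueError(
                                f"dataset /{prefix}/{channel}/{k} is missing "
                                f"required attribute {a!r}")
                    notes = [ProvenanceNote(*n) for n in
                             json.loads(d.attrs.get("notes", "[]"))]
                    traces.append(Trace(d[()], dt=float(d.attrs["dt"]),
                                        t_start=float(d.attrs["t_start"]),
                                        units=str(d.attrs["units"]),
                                        label=str(d.attrs["label"]),
                                        notes=notes))
                sets = {}
                if sets_grp is not None:
                    sets = {name: np.asarray(sets_grp[name][()], dtype=bool)
                            for name in sets_grp}
                groups = {}
                if "groups" in cgrp.attrs:
                    groups = {int(k): int(v) for k, v in
                              json.loads(cgrp.attrs["groups"]).items()}
                layout.add(SweepSet(traces, prefix=prefix, channel=channel,
                                    sets=sets, groups=groups))
        if "log" in f:
            layout.log = [CommandLogEntry(*json.loads(s))
                          for s in f["log"].asstr()[()]]
    return layout


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv(path, dt: float | None = None, units: str = "pA") -> SweepSet:
    """Read sweeps from delimited text.

    Either one column per sweep with ``dt`` supplied, or a two-column
    (time, value) file from which dt is inferred; the time column must be
    uniform to within 1 ppm.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if dt is None:
        if len(cols) != 2:
            raise ValueError("dt must be given unless the file has exactly "
                             "two columns (time, value)")
        t = df[cols[0]].to_numpy(dtype=float)
        steps = np.diff(t)
        dt_est = float(np.mean(steps))
        dev = float(np.max(np.abs(steps - dt_est)))
        if dev > 1e-6 * abs(dt_est):
            raise ValueError(f"time column is not uniform: max deviation "
                             f"{dev:g} ms from dt={dt_est:g} ms")
        return SweepSet([Trace(df[cols[1]].to_numpy(dtype=float), dt=dt_est,
                               t_start=float(t[0]), units=units,
                               label=cols[1])])
    traces = [Trace(df[c].to_numpy(dtype=float), dt=dt, units=units, label=c)
              for c in cols]
    return SweepSet(traces)


def write_csv(sweepset: SweepSet, path) -> str:
    data = {tr.label or f"sweep{k}": tr.samples
            for k, tr in enumerate(sweepset)}
    pd.DataFrame(data).to_csv(path, index=False,
                              float_format="%.17g", lineterminator="\r\n")
    return str(path)


# ---------------------------------------------------------------------------
# ABF (optional)
# ---------------------------------------------------------------------------

def import_abf(path) -> SweepSet:
    """Import an Axon Binary Format file (requires the optional pyabf)."""
    try:
        import pyabf
    except ImportError as exc:
        raise ImportError(
            "reading ABF files requires the optional dependency pyabf; "
            "install it with: pip install pyabf  (or pip install "
            "'ephyskit[abf]')") from exc
    abf = pyabf.ABF(str(path))
    dt_ms = 1000.0 / abf.dataRate
    sets: dict[str, SweepSet] = {}
    for ch in range(abf.channelCount):
        letter = chr(ord("A") + ch)
        traces = []
        for k in range(abf.sweepCount):
            abf.setSweep(k, channel=ch)
            traces.append(Trace(np.asarray(abf.sweepY, dtype=float), dt=dt_ms,
                                units=abf.adcUnits[ch] or "pA",
                                label=f"Record{letter}{k}"))
        sets[letter] = SweepSet(traces, channel=letter)
    if len(sets) == 1:
        return next(iter(sets.values()))
    merged = SweepSet([tr for s in sets.values() for tr in s])
    return merged


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["sweep", "t_cross", "t_onset", "t_peak", "peak_amp",
                  "baseline", "accepted", "reason"]


def export_event_table(events: list[EventRecord], path) -> str:
    rows = [{"sweep": e.sweep, "t_cross": e.t_cross, "t_onset": e.t_onset,
             "t_peak": e.t_peak, "peak_amp": e.peak_amp,
             "baseline": e.baseline, "accepted": e.accepted,
             "reason": e.reason} for e in events]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)
    return str(path)


def read_event_table(path) -> list[EventRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(EventRecord(int(r.sweep), float(r.t_cross),
                               None if pd.isna(r.t_onset) else float(r.t_onset),
                               None if pd.isna(r.t_peak) else float(r.t_peak),
                               None if pd.isna(r.peak_amp) else float(r.peak_amp),
                               float(r.baseline), bool(r.accepted),
                               "" if pd.isna(r.reason) else str(r.reason)))
    return out


def append_log(path, entry: CommandLogEntry) -> None:
    """Append one entry to a JSON-lines command log file."""
    with open(path, "a") as f:
        f.write(json.dumps([entry.timestamp, entry.operation, entry.params,
                            entry.outputs]) + "\n")


def read_log(path) -> list[CommandLogEntry]:
    with open(path) as f:
        return [CommandLogEntry(*json.loads(line)) for line in f
                if line.strip()]
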