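"""Reading and writing recordings and feature tables.

The package's native on-disk format is a small documented HDF5 layout
("interchange"):

    /                 attrs: cell_id, group_label, mode, format_version
    /metadata         attrs: free-form scalars (holding_pa, step_mv, ...)
    /protocol         attrs: the StepProtocol fields (absent for gap-free)
    /sweeps/NNN/command   float64 dataset, attrs: dt_ms, kind, t0_ms
    /sweeps/NNN/response  float64 dataset, attrs: dt_ms, kind, t0_ms

Units are always mV / pA / ms on disk; no trace leaves this module in any
other units.  ABF and NWB-icephys files are read through ``pyabf`` /
``pynwb`` when those optional dependencies are installed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .traces import Recording, StepProtocol, Trace

__all__ = ["write_recording", "read_recording", "write_features_table",
           "read_features_table", "IOFormatError"]

FORMAT_VERSION = 1
FEATURES_SCHEMA_VERSION = 1


class IOFormatError(IOError):
    """File could not be read under the named format."""


# ---------------------------------------------------------------------------
# interchange HDF5

def write_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["cell_id"] = rec.cell_id
        f.attrs["group_label"] = rec.group_label
        f.attrs["mode"] = rec.mode
        f.attrs["format_version"] = FORMAT_VERSION
        md = f.create_group("metadata")
        for k, v in rec.metadata.items():
            if isinstance(v, (str, int, float, bool, np.number)):
                md.attrs[k] = v
            else:
                md.attrs[k] = json.dumps(v)
        if rec.protocol is not None:
            pg = f.create_group("protocol")
            for fld in dataclasses.fields(rec.protocol):
                pg.attrs[fld.name] = getattr(rec.protocol, fld.name)
        sw = f.create_group("sweeps")
        for i, (cmd, resp) in enumerate(rec.sweeps):
            g = sw.create_group(f"{i:03d}")
            for name, tr in (("command", cmd), ("response", resp)):
                d = g.create_dataset(name, data=tr.samples, dtype="f8")
                d.attrs["dt_ms"] = tr.dt
                d.attrs["kind"] = tr.kind
                d.attrs["t0_ms"] = tr.t0
    return path


def _read_interchange(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        try:
            cell_id = str(f.attrs["cell_id"])
            mode = str(f.attrs["mode"])
        except KeyError as exc:
            raise IOFormatError(
                f"{path}: missing required attribute {exc}") from exc
        group_label = str(f.attrs.get("group_label", ""))
        metadata = {}
        if "metadata" in f:
            for k, v in f["metadata"].attrs.items():
                if isinstance(v, bytes):
                    v = v.decode()
                if isinstance(v, str) and v[:1] in "[{":
                    try:
                        v = json.loads(v)
                    except json.JSONDecodeError:
                        pass
                metadata[k] = v
        protocol = None
        if "protocol" in f:
            attrs = dict(f["protocol"].attrs)
            kwargs = {k: (v.decode() if isinstance(v, bytes) else v)
                      for k, v in attrs.items()}
            kwargs = {k: (str(v) if k == "mode" else
                          int(v) if k in ("n_steps", "count_steps") else float(v))
                      for k, v in kwargs.items()}
            protocol = StepProtocol(**kwargs)
        sweeps = []
        if "sweeps" not in f or not len(f["sweeps"]):
            raise IOFormatError(f"{path}: no sweeps")
        for key in sorted(f["sweeps"]):
            g = f["sweeps"][key]
            pair = []
            for name in ("command", "response"):
                d = g[name]
                if "dt_ms" not in d.attrs or "kind" not in d.attrs:
                    raise IOFormatError(
                        f"{path}: sweep {key}/{name} lacks unit metadata")
                kind = d.attrs["kind"]
                if isinstance(kind, bytes):
                    kind = kind.decode()
                pair.append(Trace(d[()], float(d.attrs["dt_ms"]), kind,
                                  t0=float(d.attrs.get("t0_ms", 0.0))))
            sweeps.append(tuple(pair))
    try:
        return Recording(cell_id=cell_id, group_label=group_label, mode=mode,
                         sweeps=sweeps, protocol=protocol, metadata=metadata)
    except ValueError as exc:
        raise IOFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# optional external formats

def _read_abf(path: Path, group_label: str) -> Recording:
    """Read an Axon Binary Format file via the optional ``pyabf`` reader."""
    try:
        import pyabf
    except ImportError as exc:
        raise IOFormatError(
            f"cannot read {path}: ABF support needs the optional dependency "
            "'pyabf' (pip install synaptoprobe[abf])") from exc
    abf = pyabf.ABF(str(path))
    dt_ms = 1000.0 / abf.sampleRate
    mode = "current_clamp" if "mV" in (abf.adcUnits[0] or "") else "voltage_clamp"
    resp_kind = "voltage" if mode == "current_clamp" else "current"
    cmd_kind = "current" if mode == "current_clamp" else "voltage"
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i)
        sweeps.append((Trace(np.asarray(abf.sweepC, float), dt_ms, cmd_kind),
                       Trace(np.asarray(abf.sweepY, float), dt_ms, resp_kind)))
    protocol = None
    if len(sweeps) > 1:
        protocol = _infer_protocol_from_commands(sweeps, mode)
    return Recording(cell_id=path.stem, group_label=group_label, mode=mode,
                     sweeps=sweeps, protocol=protocol,
                     metadata={"source_format": "abf"})


def _read_nwb(path: Path, group_label: str) -> Recording:
    """Read an NWB icephys file via the optional ``pynwb`` reader."""
    try:
        from pynwb import NWBHDF5IO
    except ImportError as exc:
        raise IOFormatError(
            f"cannot read {path}: NWB support needs the optional dependency "
            "'pynwb' (pip install synaptoprobe[nwb])") from exc
    with NWBHDF5IO(str(path), "r") as io:
        nwb = io.read()
        sweeps = []
        mode = "voltage_clamp"
        for series in nwb.acquisition.values():
            data = np.asarray(series.data[:], float)
            rate = getattr(series, "rate", None) or 20000.0
            dt_ms = 1000.0 / rate
            unit = (series.unit or "").lower()
            if "volt" in unit:
                mode = "current_clamp"
                resp = Trace(data * 1000.0, dt_ms, "voltage")
                cmd = Trace(np.zeros_like(data), dt_ms, "current")
            else:
                resp = Trace(data * 1e12, dt_ms, "current")
                cmd = Trace(np.zeros_like(data), dt_ms, "voltage")
            sweeps.append((cmd, resp))
        if not sweeps:
            raise IOFormatError(f"{path}: no acquisition series")
    return Recording(cell_id=path.stem, group_label=group_label, mode=mode,
                     sweeps=sweeps, protocol=None,
                     metadata={"source_format": "nwb"})


def _infer_protocol_from_commands(sweeps, mode) -> StepProtocol | None:
    """Infer a step protocol from the command channels of a sweep family."""
    cmds = [c.samples for c, _ in sweeps]
    dt = sweeps[0][0].dt
    c0 = cmds[0]
    hold = float(np.median(c0[: max(c0.size // 10, 1)]))
    levels = []
    onsets, offsets = [], []
    for c in cmds:
        dev = np.abs(c - hold) > max(0.25 * np.max(np.abs(c - hold)), 1e-9)
        if not dev.any():
            levels.append(hold)
            continue
        idx = np.nonzero(dev)[0]
        onsets.append(idx[0])
        offsets.append(idx[-1] + 1)
        levels.append(float(np.median(c[idx[0]:idx[-1] + 1])))
    if not onsets:
        return None
    incs = np.diff(levels)
    inc = float(np.median(incs)) if incs.size else 0.0
    if inc == 0.0:
        return None
    on = int(np.median(onsets))
    dur = (int(np.median(offsets)) - on) * dt
    n = len(sweeps)
    return StepProtocol(mode=mode, holding_level=hold,
                       start_offset=levels[0] - hold, increment=inc,
                       step_duration=dur, n_steps=n,
                       baseline_pre_ms=on * dt,
                       baseline_post_ms=sweeps[0][0].duration - on * dt - dur,
                       count_steps=min(17, n))


_READERS = {"interchange-hdf5": _read_interchange, "hdf5": _read_interchange,
            "h5": _read_interchange}


def read_recording(path: str | Path, format: str = "interchange-hdf5",
                   group_label: str = "") -> Recording:
    """Read a recording; units are normalized to mV/pA/ms on return.

    ``format`` is one of ``interchange-hdf5`` (``hdf5``/``h5``), ``abf``,
    ``nwb``.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    if format in _READERS:
        rec = _READERS[format](path)
        if group_label:
            rec.group_label = group_label
        return rec
    if format == "abf":
        return _read_abf(path, group_label)
    if format == "nwb":
        return _read_nwb(path, group_label)
    raise IOFormatError(f"unknown format {format!r} for {path}")


# ---------------------------------------------------------------------------
# feature tables

def write_features_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-neuron feature table as CSV.

    Missing metrics are empty fields (never 0).  A schema-version comment
    heads the file; floats use 10 significant digits so a round-trip
    preserves at least 6.
    """
    if len(df) == 0:
        raise ValueError("refusing to write an empty feature table")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# synaptoprobe features schema v{FEATURES_SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    return path


def read_features_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
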