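"""Output writers: CSV traces, HDF5 snapshot stacks, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_trace_csv(path, time, vm, vf=None) -> None:
    cols = [np.asarray(time), np.asarray(vm)]
    header = "time_ms,Vm_mV"
    if vf is not None:
        cols.append(np.asarray(vf))
        header += ",Vf_mV"
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
               comments="")


def write_multitrace_csv(path, time, traces, labels) -> None:
    """One time column plus one Vm column per sensor."""
    traces = np.atleast_2d(traces)
    header = "time_ms," + ",".join(labels)
    np.savetxt(path, np.column_stack([time, traces.T]), delimiter=",",
               header=header, comments="")


def write_trace_h5(path, time, vm, vf=None, group="trace",
                   metadata=None) -> None:
    """Multi-variable trace dump as an HDF5 group."""
    import h5py

    with h5py.File(path, "a") as fh:
        g = fh.require_group(group)
        for name, data in (("time_ms", time), ("vm_mv", vm), ("vf_mv", vf)):
            if data is None:
                continue
            if name in g:
                del g[name]
            g.create_dataset(name, data=np.asarray(data))
        for key, val in (metadata or {}).items():
            g.attrs[key] = json.dumps(val, default=str)


def write_snapshots_h5(path, times, fields, metadata=None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_ms", data=np.asarray(times))
        fh.create_dataset("vm_mv", data=np.stack(fields),
                          compression="gzip", compression_opts=4)
        for key, val in (metadata or {}).items():
            fh.attrs[key] = json.dumps(val, default=str)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def write_schedule_csv(path, rows) -> None:
    with open(path, "w") as fh:
        fh.write("pulse_time_ms,region_id\n")
        for t, rid in rows:
            fh.write(f"{t},{rid}\n")
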