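"""Readers/writers for trace CSVs, configs and run manifests.

Trace files are two-column CSVs with header ``t_ms,value`` (voltage in mV,
current in A/F).  Writing uses fixed 6-decimal formatting so that
write(read(x)) is byte-identical for canonically formatted files.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np

from . import __version__
from .trace import Trace

_FMT = "{:.6f}"


def read_trace(path, units: str = "A/F") -> Trace:
    """Read a ``t_ms,value`` CSV; malformed rows are reported by line."""
    path = Path(path)
    t, v = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "t_ms,value":
            raise ValueError(f"{path}:1: expected header 't_ms,value', "
                             f"got {header!r}")
        for ln, row in enumerate(fh, start=2):
            row = row.strip()
            if not row:
                continue
            parts = row.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, "
                                 f"got {len(parts)}")
            try:
                t.append(float(parts[0]))
                v.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    if len(t) < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    return Trace(np.asarray(t), np.asarray(v), units)


def write_trace(path, trace: Trace) -> None:
    with open(path, "w") as fh:
        fh.write("t_ms,value\n")
        for t, v in zip(trace.t, trace.value):
            fh.write(f"{_FMT.format(t)},{_FMT.format(v)}\n")


def write_manifest(path, command: str, seed=None, inputs=None,
                   extra=None) -> None:
    """Record what produced an output directory, for reproducibility."""
    manifest = {
        "command": command,
        "seed": seed,
        "inputs": inputs or {},
        "ricp_version": __version__,
        "python": platform.python_version(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
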