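"""The 10 s rapid ionic current phenotyping (RICP) voltage-clamp protocol.

The protocol is an ordered list of step/ramp segments whose labeled time
points each maximize the contribution of one target current to the total
recorded current.  The eight extraction points (label, time, min/avg) are
fixed quantities of the method; the full command waveform is shipped as a
versioned fixture file (see ``ricp/_data/ricp_protocol.csv``).  The fixture
is a reconstruction: it honours the published constraints on the waveform —
10 s total duration, the I_6mV step onset at 500 ms with its measurement
100 ms later, and the I_Kr sub-segment (750 ms at 6 mV, 7 ms at -41 mV,
then a step to 9 mV, measured at 1262 ms) — and places the remaining
current-isolating steps so that each labeled time point is dominated by its
target current (Na+ recovery/inactivation pre-pulses for I_Na/I_CaL, a long
hyperpolarisation for I_K1/I_f, a long strong depolarisation for I_Ks).
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from importlib import resources

import numpy as np

TOTAL_DURATION_MS = 10_000.0


@dataclass(frozen=True)
class Segment:
    kind: str            # "step" | "ramp"
    duration: float      # ms
    v_start: float       # mV
    v_end: float         # mV (= v_start for steps)

    def __post_init__(self):
        if self.kind not in ("step", "ramp"):
            raise ValueError(f"segment kind must be step or ramp: {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("segment duration must be > 0")
        if self.kind == "step" and self.v_start != self.v_end:
            raise ValueError("step segment requires v_start == v_end")


class VCProtocol:
    """Piecewise step/ramp command waveform."""

    def __init__(self, segments):
        self.segments = tuple(segments)
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        self.t_starts = np.concatenate(
            [[0.0], np.cumsum([s.duration for s in self.segments])])

    @property
    def total_duration(self) -> float:
        return float(self.t_starts[-1])

    def segment_index(self, t: float) -> int:
        if not 0.0 <= t < self.total_duration:
            raise ValueError(f"t={t} outside protocol [0, {self.total_duration})")
        return int(np.searchsorted(self.t_starts, t, side="right") - 1)

    def voltage_at(self, t):
        """Command voltage (mV) at time t (ms); vectorised."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        for k, tv in enumerate(t_arr):
            i = self.segment_index(tv) if tv < self.total_duration else \
                len(self.segments) - 1
            s = self.segments[i]
            frac = (tv - self.t_starts[i]) / s.duration
            frac = min(max(frac, 0.0), 1.0)
            out[k] = s.v_start + (s.v_end - s.v_start) * frac
        return out if np.ndim(t) else float(out[0])

    # --- file I/O --------------------------------------------------------
    @classmethod
    def from_csv(cls, path_or_text) -> "VCProtocol":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            fh = _io.StringIO(path_or_text)
            return cls._read(fh)
        with open(path_or_text, newline="") as fh:
            return cls._read(fh)

    @classmethod
    def _read(cls, fh) -> "VCProtocol":
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        required = {"kind", "duration_ms", "v_start_mV", "v_end_mV"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"protocol CSV must have columns {sorted(required)}")
        segs = [Segment(r["kind"], float(r["duration_ms"]),
                        float(r["v_start_mV"]), float(r["v_end_mV"]))
                for r in reader]
        return cls(segs)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kind", "duration_ms", "v_start_mV", "v_end_mV"])
            for s in self.segments:
                w.writerow([s.kind, f"{s.duration:g}",
                            f"{s.v_start:g}", f"{s.v_end:g}"])


@dataclass(frozen=True)
class TimePointSpec:
    """One labeled current-isolating extraction point: the min or average
    of the recorded current over a 2 ms window centered at t_center."""

    label: str
    t_center: float      # ms
    method: str          # "min" | "avg"
    window: float = 2.0  # ms

    def __post_init__(self):
        if self.method not in ("min", "avg"):
            raise ValueError("method must be 'min' or 'avg'")
        if not self.window > 0:
            raise ValueError("window must be > 0")


#: the eight labeled extraction points of the RICP method
_TIMEPOINTS = (
    TimePointSpec("I_6mV", 600.0, "avg"),
    TimePointSpec("I_Kr", 1262.0, "avg"),
    TimePointSpec("I_CaL", 1986.0, "min"),
    TimePointSpec("I_Na", 2760.0, "min"),
    TimePointSpec("I_to", 3641.0, "avg"),
    TimePointSpec("I_K1", 4300.0, "avg"),
    TimePointSpec("I_f", 5840.0, "avg"),
    TimePointSpec("I_Ks", 9040.0, "avg"),
)

SEGMENT_LABELS = tuple(tp.label for tp in _TIMEPOINTS)


def ricp_timepoints() -> list:
    """The eight (label, t_center, method) extraction specs, 2 ms windows."""
    return list(_TIMEPOINTS)


def ricp_protocol() -> VCProtocol:
    """Load the 10 s RICP command-waveform fixture."""
    text = resources.files("ricp._data").joinpath(
        "ricp_protocol.csv").read_text()
    prot = VCProtocol.from_csv(text)
    if prot.total_duration != TOTAL_DURATION_MS:
        raise RuntimeError("protocol fixture does not span 10 s")
    return prot
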