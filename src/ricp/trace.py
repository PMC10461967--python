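"""Sampled time-series container shared by simulation, files and features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALID_UNITS = ("mV", "A/F")


@dataclass
class Trace:
    """A sampled voltage or current trace.

    ``t`` is in ms and must be strictly increasing with at least two
    samples; ``units`` tags the value axis ("mV" or "A/F").
    """

    t: np.ndarray
    value: np.ndarray
    units: str

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.value.shape != self.t.shape:
            raise ValueError("t and value must have the same length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Values with t in [t_lo, t_hi] (boundaries inclusive)."""
        mask = (self.t >= t_lo) & (self.t <= t_hi)
        return self.value[mask]

    def shifted(self, dt: float) -> "Trace":
        return Trace(self.t + dt, self.value.copy(), self.units)
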