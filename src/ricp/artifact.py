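"""Patch-clamp measurement-chain model.

The voltage-clamp recording is corrupted by a small set of artifacts that
are modeled explicitly:

* **seal leak** — an ohmic current through the imperfect pipette-membrane
  seal, reversal 0 mV, conductance 1/R_seal;
* **liquid junction potential** — a constant offset V_ljp between the
  commanded and true membrane potential;
* **access resistance with partial series-resistance compensation** — the
  membrane charges through the residual resistance (1 - comp_frac) *
  R_access, so command steps reach the membrane with a first-order lag and
  a steady-state divider error R_seal / (R_seal + R_residual);
* **supercharging** — command pre-shaping that drives the membrane to the
  step target within one sample at protocol edges.

This module is deterministic; measurement noise belongs to the synthetic
cohort generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass
class ArtifactParameters:
    """What corrupts the measurement (study defaults from the recording
    configuration: 2 GOhm seal, 20 MOhm access, 70% compensation,
    -2.8 mV junction offset, supercharging on)."""

    R_seal: float = 2.0          # GOhm
    R_access: float = 20.0       # MOhm
    comp_frac: float = 0.70
    V_ljp: float = -2.8          # mV
    supercharging: bool = True
    C_m: float = 45.0            # pF

    def __post_init__(self):
        if not self.R_seal > 0:
            raise ValueError("R_seal must be > 0")
        if self.R_access < 0:
            raise ValueError("R_access must be >= 0")
        if not 0.0 <= self.comp_frac <= 1.0:
            raise ValueError("comp_frac must be in [0, 1]")

    @property
    def R_residual_gohm(self) -> float:
        """Uncompensated access resistance in GOhm."""
        return (1.0 - self.comp_frac) * self.R_access * 1.0e-3

    @property
    def divider(self) -> float:
        """Steady-state attenuation of the command by the seal/access
        voltage divider (1 for a perfect seal or zero residual R)."""
        if not np.isfinite(self.R_seal):
            return 1.0
        return self.R_seal / (self.R_seal + self.R_residual_gohm)

    @classmethod
    def ideal(cls, C_m: float = 45.0) -> "ArtifactParameters":
        """Artifact-free limit: no access resistance, no leak, no offset."""
        return cls(R_seal=np.inf, R_access=0.0, comp_frac=1.0,
                   V_ljp=0.0, supercharging=True, C_m=C_m)

    def to_dict(self) -> dict:
        return {
            "R_seal_GOhm": self.R_seal if np.isfinite(self.R_seal) else None,
            "R_access_MOhm": self.R_access,
            "comp_frac": self.comp_frac,
            "V_ljp_mV": self.V_ljp,
            "supercharging": self.supercharging,
            "C_m_pF": self.C_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArtifactParameters":
        r_seal = d.get("R_seal_GOhm")
        return cls(
            R_seal=np.inf if r_seal is None else r_seal,
            R_access=d.get("R_access_MOhm", 20.0),
            comp_frac=d.get("comp_frac", 0.70),
            V_ljp=d.get("V_ljp_mV", -2.8),
            supercharging=d.get("supercharging", True),
            C_m=d.get("C_m_pF", 45.0),
        )

    @classmethod
    def from_json(cls, path) -> "ArtifactParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def leak_current(v_mV, r_seal_gohm: float):
    """Seal-leak current in pA for a membrane potential in mV.

    Ohm's law with a 0 mV reversal: I = V / R_seal (mV / GOhm = pA), so the
    current is negative (inward) at negative potentials.
    """
    if not r_seal_gohm > 0:
        raise ValueError("R_seal must be > 0")
    return np.asarray(v_mV, dtype=float) / r_seal_gohm if np.ndim(v_mV) \
        else float(v_mV) / r_seal_gohm
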