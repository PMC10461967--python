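"""Baseline iPSC-CM model profiles and parameter handling.

Two baseline profiles are shipped:

``kernik``
    A reconstruction of the Kernik-Clancy baseline iPSC-CM model: its
    current composition (including the T-type Ca2+ current), published
    baseline maximal conductance densities (e.g. g_Kr = 0.218025 nS/pF,
    g_K1 = 0.13379 nS/pF, g_Na = 9.7206 nS/pF), compartment volumes scaled
    from the ten Tusscher geometry, and a GHK L-type Ca2+ flux.  Gate
    kinetics are taken from the parent formulations the source model was
    fit from (see :mod:`ricp._core`); the L-type permeability is calibrated
    to the source model's peak current density (~ -5 A/F at 0 mV).

``paci``
    The corresponding reconstruction of the Paci (2013, ventricular-like)
    baseline conductance profile, with its larger exchanger/funny currents,
    smaller delayed rectifiers, weak hERG inactivation and no T-type
    current.

Both profiles run with the study configuration: C_m = 45 pF, fixed
intracellular Na+/K+ (values found by 1000 s of current-clamp
initialisation), and per-current conductance multipliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import _core
from ._core import NPARAM, NSTATE

#: currents whose conductance can be scaled by a multiplier
MULTIPLIER_KEYS = (
    "I_Na", "I_CaL", "I_Kr", "I_Ks", "I_to", "I_K1", "I_f",
    "I_NaCa", "I_NaK", "I_bNa", "I_bCa", "I_leak", "I_CaT", "I_PCa",
)

#: the twelve conductances sampled in the population analysis
SAMPLED_CONDUCTANCES = (
    "I_Na", "I_CaL", "I_Kr", "I_Ks", "I_to", "I_K1", "I_f",
    "I_leak", "I_NaCa", "I_NaK", "I_bNa", "I_bCa",
)

CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_CaT", "I_Kr", "I_Ks", "I_to", "I_K1", "I_f",
    "I_NaCa", "I_NaK", "I_bNa", "I_bCa", "I_PCa", "I_leak", "I_total",
)

STATE_NAMES = (
    "V", "Cai", "CaSR", "Nai", "Ki", "m", "h", "j", "d", "f", "fCa",
    "g_rel", "Xr1", "Xr2", "Xs", "Xf", "r_to", "s_to", "dT", "fT",
)

_PROFILES = {
    "kernik": dict(
        g_Na=9.720613409241,
        p_CaL=1.0e-4,
        g_CaT=0.185,
        g_Kr=0.218025,
        g_Ks=0.0077,
        g_to=0.117833333333333,
        g_K1=0.133785777797606,
        g_f=0.0435,
        k_NaCa=1100.0,
        P_NaK=2.4761,
        g_bNa=0.00029727,
        g_bCa=0.000592,
        g_PCa=0.2625,
        C_m_base=60.0,
        Vc_base=3712.36,
        VSR_base=247.64,
        Nao=140.0,
        Ko=5.4,
        Cao=1.8,
        E_f=-17.0,
        xr2_slope=24.0,
        xr2_vhalf=-88.0,
        xr2_slowdeact=4.0,
        k1_vhalf=10.0,
        k1_slope=8.0,
        xf_vhalf=-85.0,
        xf_slope=5.0,
        na_shape=0.0,
        k1_tail=0.12,
        Nai_default=7.17,
        Ki_default=104.75,
    ),
    "paci": dict(
        g_Na=3.6712302,
        p_CaL=8.635702e-5,
        g_CaT=0.0,
        g_Kr=0.0298667,
        g_Ks=0.002041,
        g_to=0.0299038,
        g_K1=0.0281492,
        g_f=0.03010312,
        k_NaCa=1200.0,
        P_NaK=1.841424,
        g_bNa=0.0009,
        g_bCa=0.00069264,
        g_PCa=0.4125,
        C_m_base=98.7109,
        Vc_base=8800.0,
        VSR_base=583.73,
        Nao=151.0,
        Ko=5.4,
        Cao=1.8,
        E_f=-17.0,
        xr2_slope=50.0,
        xr2_vhalf=-88.0,
        xr2_slowdeact=4.0,
        k1_vhalf=45.0,
        k1_slope=15.0,
        xf_vhalf=-77.85,
        xf_slope=5.0,
        na_shape=1.0,
        k1_tail=0.2,
        Nai_default=10.9,
        Ki_default=150.0,
    ),
}

MODEL_IDS = tuple(_PROFILES)


def _default_multipliers() -> dict:
    return {k: 1.0 for k in MULTIPLIER_KEYS}


@dataclass
class ModelParameters:
    """The knobs of one in silico cell.

    ``multipliers`` scale each current's maximal conductance relative to the
    profile baseline; ``g_Kr_base`` exposes the baseline I_Kr conductance
    density (nS/pF) so absolute g_Kr values can be mapped to multipliers.
    """

    model_id: str = "kernik"
    multipliers: dict = field(default_factory=_default_multipliers)
    C_m: float = 45.0
    Na_i_fixed: float | None = None
    K_i_fixed: float | None = None
    g_Kr_base: float | None = None

    def __post_init__(self):
        if self.model_id not in _PROFILES:
            raise ValueError(f"unknown model_id: {self.model_id!r}")
        prof = _PROFILES[self.model_id]
        full = _default_multipliers()
        for k, v in self.multipliers.items():
            if k not in full:
                raise ValueError(f"unknown current in multipliers: {k!r}")
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"multiplier for {k} must be finite and >= 0")
            full[k] = float(v)
        self.multipliers = full
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.g_Kr_base is None:
            self.g_Kr_base = prof["g_Kr"]
        if self.Na_i_fixed is None or self.K_i_fixed is None:
            nai, ki = _default_concentrations(self.model_id)
            if self.Na_i_fixed is None:
                self.Na_i_fixed = nai
            if self.K_i_fixed is None:
                self.K_i_fixed = ki
        if self.Na_i_fixed <= 0 or self.K_i_fixed <= 0:
            raise ValueError("fixed concentrations must be positive")

    @property
    def profile(self) -> dict:
        return _PROFILES[self.model_id]

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "multipliers": dict(self.multipliers),
            "C_m_pF": self.C_m,
            "fixed_concentrations_mM": {
                "Na_i": self.Na_i_fixed, "K_i": self.K_i_fixed,
            },
            "g_Kr_base_nS_per_pF": self.g_Kr_base,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        conc = d.get("fixed_concentrations_mM", {})
        return cls(
            model_id=d["model_id"],
            multipliers=dict(d.get("multipliers", {})),
            C_m=d.get("C_m_pF", 45.0),
            Na_i_fixed=conc.get("Na_i"),
            K_i_fixed=conc.get("K_i"),
            g_Kr_base=d.get("g_Kr_base_nS_per_pF"),
        )


def _data_text(name: str) -> str | None:
    ref = resources.files("ricp._data").joinpath(name)
    try:
        return ref.read_text()
    except (FileNotFoundError, ModuleNotFoundError):
        return None


def _default_concentrations(model_id: str) -> tuple:
    txt = _data_text(f"{model_id}_init.json")
    if txt is not None:
        d = json.loads(txt)
        return d["Na_i_mM"], d["K_i_mM"]
    prof = _PROFILES[model_id]
    return prof["Nai_default"], prof["Ki_default"]


def default_state(model_id: str) -> np.ndarray:
    """Baseline initial state (after 1000 s current-clamp initialisation
    when the shipped cache is present, otherwise a resting-state guess)."""
    txt = _data_text(f"{model_id}_init.json")
    if txt is not None:
        d = json.loads(txt)
        y = np.asarray(d["state"], dtype=float)
        if y.shape == (NSTATE,):
            return y
    return seed_state(model_id)


def seed_state(model_id: str) -> np.ndarray:
    """A crude diastolic state used to bootstrap initialisation."""
    prof = _PROFILES[model_id]
    y = np.zeros(NSTATE)
    y[0] = -75.0
    y[1] = 0.0002
    y[2] = 2.0
    y[3] = prof["Nai_default"]
    y[4] = prof["Ki_default"]
    y[5:] = [0.03, 0.7, 0.7, 0.0002, 0.95, 0.99, 1.0,
             0.001, 0.78, 0.02, 0.3, 0.0, 0.99, 0.0003, 0.9]
    return y


def pack_parameters(params: ModelParameters,
                    r_seal_gohm: float = np.inf,
                    stim_amp: float = 0.0,
                    stim_period: float = 1000.0,
                    stim_dur: float = 5.0,
                    fix_concentrations: bool = True,
                    c_m: float | None = None) -> np.ndarray:
    """Flatten model + leak configuration into the numba parameter vector.

    The seal-leak conductance density is ``I_leak`` multiplier divided by
    (R_seal * C_m); volumes scale proportionally to C_m so that current
    densities and Ca2+ handling are independent of cell size.  ``c_m``
    overrides the model capacitance (used when the recording chain sees a
    different capacitance than the model's configured 45 pF).
    """
    cm_eff = params.C_m if c_m is None else float(c_m)
    prof = params.profile
    mult = params.multipliers
    p = np.zeros(NPARAM)
    p[_core.P_G_NA] = prof["g_Na"] * mult["I_Na"]
    p[_core.P_P_CAL] = prof["p_CaL"] * mult["I_CaL"]
    p[_core.P_G_CAT] = prof["g_CaT"] * mult["I_CaT"]
    p[_core.P_G_KR] = params.g_Kr_base * mult["I_Kr"]
    p[_core.P_G_KS] = prof["g_Ks"] * mult["I_Ks"]
    p[_core.P_G_TO] = prof["g_to"] * mult["I_to"]
    p[_core.P_G_K1] = prof["g_K1"] * mult["I_K1"]
    p[_core.P_G_F] = prof["g_f"] * mult["I_f"]
    p[_core.P_K_NACA] = prof["k_NaCa"] * mult["I_NaCa"]
    p[_core.P_P_NAK] = prof["P_NaK"] * mult["I_NaK"]
    p[_core.P_G_BNA] = prof["g_bNa"] * mult["I_bNa"]
    p[_core.P_G_BCA] = prof["g_bCa"] * mult["I_bCa"]
    p[_core.P_G_PCA] = prof["g_PCa"] * mult["I_PCa"]
    if np.isfinite(r_seal_gohm):
        if r_seal_gohm <= 0:
            raise ValueError("R_seal must be positive")
        p[_core.P_G_SEAL] = mult["I_leak"] / (r_seal_gohm * cm_eff)
    else:
        p[_core.P_G_SEAL] = 0.0
    p[_core.P_CM] = cm_eff
    scale = cm_eff / prof["C_m_base"]
    p[_core.P_VC] = prof["Vc_base"] * scale
    p[_core.P_VSR] = prof["VSR_base"] * scale
    p[_core.P_NAO] = prof["Nao"]
    p[_core.P_KO] = prof["Ko"]
    p[_core.P_CAO] = prof["Cao"]
    p[_core.P_NAI_FIX] = params.Na_i_fixed
    p[_core.P_KI_FIX] = params.K_i_fixed
    p[_core.P_FIX_CONC] = 1.0 if fix_concentrations else 0.0
    p[_core.P_STIM_AMP] = stim_amp
    p[_core.P_STIM_PERIOD] = stim_period
    p[_core.P_STIM_DUR] = stim_dur
    p[_core.P_E_F] = prof["E_f"]
    p[_core.P_XR2_SLOPE] = prof["xr2_slope"]
    p[_core.P_K1_VHALF] = prof["k1_vhalf"]
    p[_core.P_K1_SLOPE] = prof["k1_slope"]
    p[_core.P_XF_VHALF] = prof["xf_vhalf"]
    p[_core.P_XF_SLOPE] = prof["xf_slope"]
    p[_core.P_NA_SHAPE] = prof["na_shape"]
    p[_core.P_K1_TAIL] = prof["k1_tail"]
    p[_core.P_XR2_VHALF] = prof["xr2_vhalf"]
    p[_core.P_XR2_SLOWDEACT] = prof["xr2_slowdeact"]
    return p


def rhs(state: np.ndarray, params: ModelParameters,
        v_clamp: float | None = None,
        r_seal_gohm: float = np.inf) -> tuple:
    """Evaluate the model right-hand side at one state.

    Returns ``(dstate, currents)`` where ``currents`` maps each named
    current density (A/F) plus ``I_total``.  With ``v_clamp`` given the
    membrane potential is externally imposed (dV/dt entry is 0).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (NSTATE,):
        raise ValueError(f"state must have {NSTATE} entries")
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state passed to rhs")
    p = pack_parameters(params, r_seal_gohm=r_seal_gohm)
    if v_clamp is None:
        dy, cur = _core.compute(0.0, state, p, _core.MODE_CC,
                                0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    else:
        dy, cur = _core.compute(0.0, state, p, _core.MODE_VC_IDEAL,
                                float(v_clamp), float(v_clamp), 0.0, 1.0,
                                0.0, 0.0)
    names = ("I_Na", "I_CaL", "I_CaT", "I_Kr", "I_Ks", "I_to", "I_K1",
             "I_f", "I_NaCa", "I_NaK", "I_bNa", "I_bCa", "I_PCa",
             "I_leak", "I_total")
    currents = {n: cur[i] for i, n in enumerate(names)}
    return dy, currents
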