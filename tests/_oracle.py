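"""Independent plain-numpy transcription of the membrane-model equations.

Written separately from ricp._core (dictionary-based, per-current
functions) so that coding slips in the compiled right-hand side are caught
by comparison at random states.  Only the published constants are shared.
"""

import numpy as np

F = 96485.3415
R = 8.314472
T = 310.0
RTF = R * T / F * 1000.0        # mV
FRT = 1.0 / RTF                 # 1/mV


def gates_inf_tau(v, prof):
    """Steady states and time constants of every gate at potential v."""
    g = {}
    if prof["na_shape"] == 1.0:
        m_inf = (1.0 / (1.0 + np.exp((-v - 34.1) / 5.9))) ** (1.0 / 3.0)
        h_inf = 1.0 / np.sqrt(1.0 + np.exp((v + 72.1) / 5.7))
    else:
        m_inf = (1.0 + np.exp((-56.86 - v) / 9.03)) ** -2
        h_inf = (1.0 + np.exp((v + 71.55) / 7.43)) ** -2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    g["m"] = (m_inf, am * bm)
    if v < -40.0:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    g["h"] = (h_inf, 1.0 / (ah + bh))
    if v < -40.0:
        aj = (-2.5428e4 * np.exp(0.2444 * v)
              - 6.948e-6 * np.exp(-0.04391 * v)) * (v + 37.78) \
            / (1.0 + np.exp(0.311 * (v + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * v) \
            / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    g["j"] = (h_inf, 1.0 / (aj + bj))

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    g["d"] = (d_inf, ad * bd + gd)
    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = 1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0) \
        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0)) \
        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0
    g["f"] = (f_inf, tau_f)

    g["xr1"] = (1.0 / (1.0 + np.exp((-26.0 - v) / 7.0)),
                450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
                * 6.0 / (1.0 + np.exp((v + 30.0) / 11.5)))
    g["xr2"] = (1.0 / (1.0 + np.exp((v - prof["xr2_vhalf"])
                                    / prof["xr2_slope"])),
                3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
                * 1.12 / (1.0 + np.exp((v - 60.0) / 20.0)))
    g["xs"] = (1.0 / (1.0 + np.exp((-5.0 - v) / 14.0)),
               1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
               / (1.0 + np.exp((v - 35.0) / 15.0)) + 80.0)
    g["xf"] = (1.0 / (1.0 + np.exp((v - prof["xf_vhalf"]) / prof["xf_slope"])),
               1900.0 / (1.0 + np.exp((v + 15.0) / 10.0)) + 15.0)
    g["r"] = (1.0 / (1.0 + np.exp((20.0 - v) / 6.0)),
              9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8)
    g["s"] = (1.0 / (1.0 + np.exp((v + 30.0) / 5.0)),
              500.0 * np.exp(-((v + 67.0) ** 2) / 1000.0) + 30.0)
    g["dT"] = (1.0 / (1.0 + np.exp(-(v + 26.3) / 6.0)),
               1.0 / (1.068 * np.exp((v + 26.3) / 30.0)
                      + 1.068 * np.exp(-(v + 26.3) / 30.0)))
    g["fT"] = (1.0 / (1.0 + np.exp((v + 61.7) / 5.6)),
               1.0 / (0.0153 * np.exp(-(v + 61.7) / 83.3)
                      + 0.015 * np.exp((v + 61.7) / 15.38)))
    return g


def currents(v, state, prof, mult, c_m, nai, ki, r_seal=np.inf):
    """Named current densities (A/F) at one state."""
    cai = max(state["Cai"], 1e-9)
    nao, ko, cao = prof["Nao"], prof["Ko"], prof["Cao"]
    e_na = RTF * np.log(nao / nai)
    e_k = RTF * np.log(ko / ki)
    e_ca = 0.5 * RTF * np.log(cao / cai)
    e_ks = RTF * np.log((ko + 0.03 * nao) / (ki + 0.03 * nai))

    out = {}
    out["I_Na"] = prof["g_Na"] * mult["I_Na"] * state["m"] ** 3 \
        * state["h"] * state["j"] * (v - e_na)
    x = 2.0 * v * FRT
    if abs(x) < 1e-7:
        flux = 2.0 * F * (cai - 0.341 * cao)
    else:
        flux = 4.0 * (v / 1000.0) * F ** 2 / (R * T) \
            * (cai * np.exp(x) - 0.341 * cao) / (np.exp(x) - 1.0)
    out["I_CaL"] = prof["p_CaL"] * mult["I_CaL"] * flux \
        * state["d"] * state["f"] * state["fCa"]
    out["I_CaT"] = prof["g_CaT"] * mult["I_CaT"] * state["dT"] \
        * state["fT"] * (v - e_ca)
    out["I_Kr"] = prof["g_Kr"] * mult["I_Kr"] * np.sqrt(ko / 5.4) \
        * state["Xr1"] * state["Xr2"] * (v - e_k)
    out["I_Ks"] = prof["g_Ks"] * mult["I_Ks"] * state["Xs"] ** 2 * (v - e_ks)
    out["I_to"] = prof["g_to"] * mult["I_to"] * state["r_to"] \
        * state["s_to"] * (v - e_k)
    vmek = v - e_k
    tail = prof["k1_tail"]
    xk1 = (1.0 - tail) / (1.0 + np.exp((vmek - prof["k1_vhalf"])
                                       / prof["k1_slope"])) \
        + tail * np.exp(-((vmek - 50.0) / 18.0) ** 2)
    out["I_K1"] = prof["g_K1"] * mult["I_K1"] * np.sqrt(ko / 5.4) \
        * xk1 * vmek
    out["I_f"] = prof["g_f"] * mult["I_f"] * state["Xf"] * (v - prof["E_f"])
    e1 = np.exp(0.35 * v * FRT)
    e2 = np.exp(-0.65 * v * FRT)
    out["I_NaCa"] = prof["k_NaCa"] * mult["I_NaCa"] \
        * (e1 * nai ** 3 * cao - e2 * nao ** 3 * cai * 2.5) \
        / ((87.5 ** 3 + nao ** 3) * (1.38 + cao) * (1.0 + 0.1 * e2))
    out["I_NaK"] = prof["P_NaK"] * mult["I_NaK"] * ko * nai \
        / ((ko + 1.0) * (nai + 40.0)
           * (1.0 + 0.1245 * np.exp(-0.1 * v * FRT)
              + 0.0353 * np.exp(-v * FRT)))
    out["I_bNa"] = prof["g_bNa"] * mult["I_bNa"] * (v - e_na)
    out["I_bCa"] = prof["g_bCa"] * mult["I_bCa"] * (v - e_ca)
    out["I_PCa"] = prof["g_PCa"] * mult["I_PCa"] * cai / (cai + 0.0005)
    if np.isfinite(r_seal):
        out["I_leak"] = mult["I_leak"] * v / (r_seal * c_m)
    else:
        out["I_leak"] = 0.0
    out["I_total"] = sum(out.values())
    return out
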