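"""Numba-compiled right-hand side of the iPSC-CM membrane model.

The model is a Hodgkin-Huxley-type ordinary differential equation system for
an induced pluripotent stem cell derived cardiomyocyte (iPSC-CM).  Two
baseline parameter profiles are provided by :mod:`ricp.models`: one
reproducing the conductance balance, compartment volumes and GHK L-type
formulation of the Kernik-Clancy baseline iPSC-CM model, and one reproducing
the Paci (2013, ventricular-like) baseline.  Gate kinetics follow the parent
formulations those models were derived from (ten Tusscher 2004/2006 for
I_Na/I_CaL/I_to/I_Kr/I_Ks and Ca2+ handling, Shannon/Demir for the T-type
Ca2+ current, the Paci funny-current gate), with a small number of
profile-level kinetic constants (hERG inactivation slope, inward-rectifier
rectification midpoint) that differ between the two profiles.

Units: membrane potential mV, time ms, concentrations mM, currents A/F
(= pA/pF), capacitance pF, volumes um^3, seal resistance GOhm.

State vector layout (20 entries)::

    0  V      membrane potential (mV)
    1  Cai    free cytosolic Ca2+ (mM)
    2  CaSR   free sarcoplasmic-reticulum Ca2+ (mM)
    3  Nai    intracellular Na+ (mM)
    4  Ki     intracellular K+ (mM)
    5  m, 6 h, 7 j          I_Na gates
    8  d, 9 f, 10 fCa       I_CaL gates
    11 g_rel                CICR release gate
    12 Xr1, 13 Xr2          I_Kr activation / inactivation
    14 Xs                   I_Ks activation
    15 Xf                   I_f activation
    16 r_to, 17 s_to        I_to activation / inactivation
    18 dT, 19 fT            I_CaT gates

Parameter vector layout: see P_* index constants below.
"""

import numpy as np
from numba import njit

NSTATE = 20

# physical constants
F_SI = 96485.3415        # C/mol
R_GAS = 8.314472         # J/(mol K)
TEMP = 310.0             # K
FRT_MV = F_SI / (R_GAS * TEMP) / 1000.0   # 1/mV

# parameter-vector indices
P_G_NA = 0        # nS/pF
P_P_CAL = 1       # m^3/(F s), GHK prefactor convention
P_G_CAT = 2
P_G_KR = 3
P_G_KS = 4
P_G_TO = 5
P_G_K1 = 6
P_G_F = 7
P_K_NACA = 8      # A/F
P_P_NAK = 9       # A/F
P_G_BNA = 10
P_G_BCA = 11
P_G_PCA = 12      # A/F
P_G_SEAL = 13     # A/F per mV (= 1/(R_seal[GOhm] * C_m[pF]))
P_CM = 14         # pF
P_VC = 15         # um^3
P_VSR = 16        # um^3
P_NAO = 17        # mM
P_KO = 18
P_CAO = 19
P_NAI_FIX = 20
P_KI_FIX = 21
P_FIX_CONC = 22   # 1.0 -> [Na]i/[K]i clamped
P_STIM_AMP = 23   # A/F, depolarizing positive
P_STIM_PERIOD = 24  # ms
P_STIM_DUR = 25   # ms
P_E_F = 26        # funny-current reversal, mV
P_XR2_SLOPE = 27  # hERG inactivation slope, mV
P_K1_VHALF = 28   # inward-rectifier rectification midpoint, mV above E_K
P_K1_SLOPE = 29
P_XF_VHALF = 30   # funny-current activation midpoint, mV
P_XF_SLOPE = 31
P_NA_SHAPE = 32   # 0: ten Tusscher steady states, 1: Paci sqrt-form
P_K1_TAIL = 33    # weak-rectification fraction of I_K1
P_XR2_VHALF = 34  # hERG inactivation midpoint, mV
P_XR2_SLOWDEACT = 35  # fold slowing of hERG deactivation at diastolic V
NPARAM = 36

# current indices in the per-evaluation current vector
I_NA, I_CAL, I_CAT, I_KR, I_KS, I_TO, I_K1, I_F, I_NACA, I_NAK, \
    I_BNA, I_BCA, I_PCA, I_SEAL, I_TOTAL = range(15)
NCURRENT = 15

# clamp modes
MODE_CC = 0       # current clamp (V is a state)
MODE_VC_RS = 1    # voltage clamp through residual series resistance (V is a state)
MODE_VC_IDEAL = 2  # ideal clamp (V imposed by the command)

# Ca2+ handling constants (ten Tusscher 2004)
_VMAX_UP = 0.000425   # mM/ms
_K_UP = 0.00025       # mM
_V_LEAK_SR = 8.0e-5   # 1/ms
_A_REL = 0.016464     # mM/ms
_B_REL = 0.25         # mM
_C_REL = 0.008232     # mM/ms
_BUF_C = 0.15         # mM
_K_BUF_C = 0.001      # mM
_BUF_SR = 10.0        # mM
_K_BUF_SR = 0.3       # mM
_NA_FRAC_F = 0.491 / 1.491   # Na+ fraction of the funny current


@njit(cache=True)
def command_voltage(t, v0, v1, t0, dur):
    """Linear command voltage within one protocol segment."""
    if dur <= 0.0:
        return v0
    return v0 + (v1 - v0) * (t - t0) / dur


@njit(cache=True)
def compute(t, y, p, mode, v0, v1, t0, dur, ru_gohm, v_ljp):
    """Evaluate state derivative and membrane currents.

    Returns ``(dy, cur)`` where ``cur`` holds the named current densities
    (A/F) listed by the ``I_*`` index constants.  ``ru_gohm`` is the residual
    (uncompensated) access resistance in GOhm; it is only used in
    ``MODE_VC_RS``.
    """
    dy = np.zeros(NSTATE)
    cur = np.zeros(NCURRENT)

    if mode == MODE_VC_IDEAL:
        v = command_voltage(t, v0, v1, t0, dur) + v_ljp
    else:
        v = y[0]

    cai = y[1]
    casr = y[2]
    if p[P_FIX_CONC] == 1.0:
        nai = p[P_NAI_FIX]
        ki = p[P_KI_FIX]
    else:
        nai = y[3]
        ki = y[4]
    m, h, jg = y[5], y[6], y[7]
    d, f, fca = y[8], y[9], y[10]
    grel = y[11]
    xr1, xr2 = y[12], y[13]
    xs = y[14]
    xf = y[15]
    rto, sto = y[16], y[17]
    dt_g, ft_g = y[18], y[19]

    nao = p[P_NAO]
    ko = p[P_KO]
    cao = p[P_CAO]

    if cai < 1.0e-9:
        cai = 1.0e-9
    if casr < 1.0e-9:
        casr = 1.0e-9

    rtf = 1.0 / FRT_MV  # mV
    e_na = rtf * np.log(nao / nai)
    e_k = rtf * np.log(ko / ki)
    e_ca = 0.5 * rtf * np.log(cao / cai)
    pkna = 0.03
    e_ks = rtf * np.log((ko + pkna * nao) / (ki + pkna * nai))

    # --- fast Na+ current (ten Tusscher 2006 kinetics) ------------------
    if p[P_NA_SHAPE] == 1.0:
        m_inf = (1.0 / (1.0 + np.exp((-v - 34.1) / 5.9))) ** (1.0 / 3.0)
    else:
        m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    b_m = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m
    if p[P_NA_SHAPE] == 1.0:
        h_inf = 1.0 / np.sqrt(1.0 + np.exp((v + 72.1) / 5.7))
    else:
        h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        a_h = 0.057 * np.exp(-(v + 80.0) / 6.8)
        b_h = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    tau_h = 1.0 / (a_h + b_h)
    j_inf = h_inf
    if v < -40.0:
        a_j = (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23)))
        b_j = 0.02424 * np.exp(-0.01052 * v) \
            / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    else:
        a_j = 0.0
        b_j = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    tau_j = 1.0 / (a_j + b_j)
    i_na = p[P_G_NA] * m ** 3 * h * jg * (v - e_na)

    # --- L-type Ca2+ current, GHK driving term --------------------------
    v_volt = v * 1.0e-3
    x = 2.0 * v * FRT_MV
    if np.abs(x) < 1.0e-7:
        ghk = 2.0 * F_SI * (cai - 0.341 * cao)
    else:
        ghk = 4.0 * v_volt * F_SI * F_SI / (R_GAS * TEMP) \
            * (cai * np.exp(x) - 0.341 * cao) / (np.exp(x) - 1.0)
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = 1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0) \
        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0)) \
        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0
    a_fca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    b_fca = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    g_fca = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    fca_inf = (a_fca + b_fca + g_fca + 0.23) / 1.46
    tau_fca = 2.0
    i_cal = p[P_P_CAL] * ghk * d * f * fca

    # --- T-type Ca2+ current (Shannon/Demir kinetics) -------------------
    dt_inf = 1.0 / (1.0 + np.exp(-(v + 26.3) / 6.0))
    tau_dt = 1.0 / (1.068 * np.exp((v + 26.3) / 30.0)
                    + 1.068 * np.exp(-(v + 26.3) / 30.0))
    ft_inf = 1.0 / (1.0 + np.exp((v + 61.7) / 5.6))
    tau_ft = 1.0 / (0.0153 * np.exp(-(v + 61.7) / 83.3)
                    + 0.015 * np.exp((v + 61.7) / 15.38))
    i_cat = p[P_G_CAT] * dt_g * ft_g * (v - e_ca)

    # --- rapid delayed rectifier K+ current -----------------------------
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    a_xr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    # slow hERG deactivation at diastolic potentials (tau ~ seconds)
    slow_deact = 1.0 + p[P_XR2_SLOWDEACT] / (1.0 + np.exp((v + 50.0) / 8.0))
    tau_xr1 = a_xr1 * b_xr1 * slow_deact
    xr2_inf = 1.0 / (1.0 + np.exp((v - p[P_XR2_VHALF]) / p[P_XR2_SLOPE]))
    a_xr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2
    i_kr = p[P_G_KR] * np.sqrt(ko / 5.4) * xr1 * xr2 * (v - e_k)

    # --- slow delayed rectifier K+ current ------------------------------
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0
    i_ks = p[P_G_KS] * xs * xs * (v - e_ks)

    # --- transient outward K+ current -----------------------------------
    # inactivation slowed relative to adult epicardium to reflect the
    # slower I_to decay of iPSC-CMs
    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + np.exp((v + 30.0) / 5.0))
    tau_s = 500.0 * np.exp(-((v + 67.0) ** 2) / 1000.0) + 30.0
    i_to = p[P_G_TO] * rto * sto * (v - e_k)

    # --- inward rectifier K+ current ------------------------------------
    vmek = v - e_k
    # strong rectification plus a weak-rectification tail that carries a
    # small outward component up to ~ -30 mV
    tail = p[P_K1_TAIL]
    xk1_inf = (1.0 - tail) / (1.0 + np.exp((vmek - p[P_K1_VHALF])
                                           / p[P_K1_SLOPE])) \
        + tail * np.exp(-((vmek - 50.0) / 18.0) ** 2)
    i_k1 = p[P_G_K1] * np.sqrt(ko / 5.4) * xk1_inf * vmek

    # --- funny current ---------------------------------------------------
    xf_inf = 1.0 / (1.0 + np.exp((v - p[P_XF_VHALF]) / p[P_XF_SLOPE]))
    tau_xf = 1900.0 / (1.0 + np.exp((v + 15.0) / 10.0)) + 15.0
    i_f = p[P_G_F] * xf * (v - p[P_E_F])
    i_f_na = _NA_FRAC_F * i_f
    i_f_k = i_f - i_f_na

    # --- Na+/Ca2+ exchanger (ten Tusscher formulation) ------------------
    g_ncx = 0.35
    k_sat = 0.1
    km_nai = 87.5
    km_ca = 1.38
    alpha_ncx = 2.5
    e1 = np.exp(g_ncx * v * FRT_MV)
    e2 = np.exp((g_ncx - 1.0) * v * FRT_MV)
    i_naca = p[P_K_NACA] * (e1 * nai ** 3 * cao - e2 * nao ** 3 * cai * alpha_ncx) \
        / ((km_nai ** 3 + nao ** 3) * (km_ca + cao) * (1.0 + k_sat * e2))

    # --- Na+/K+ pump ------------------------------------------------------
    i_nak = p[P_P_NAK] * ko * nai \
        / ((ko + 1.0) * (nai + 40.0)
           * (1.0 + 0.1245 * np.exp(-0.1 * v * FRT_MV)
              + 0.0353 * np.exp(-v * FRT_MV)))

    # --- background and pump Ca2+ currents -------------------------------
    i_bna = p[P_G_BNA] * (v - e_na)
    i_bca = p[P_G_BCA] * (v - e_ca)
    i_pca = p[P_G_PCA] * cai / (cai + 0.0005)

    # --- seal-leak artifact current (reversal 0 mV) ----------------------
    i_seal = p[P_G_SEAL] * v

    i_ion = i_na + i_cal + i_cat + i_kr + i_ks + i_to + i_k1 + i_f \
        + i_naca + i_nak + i_bna + i_bca + i_pca
    i_total = i_ion + i_seal

    cur[I_NA] = i_na
    cur[I_CAL] = i_cal
    cur[I_CAT] = i_cat
    cur[I_KR] = i_kr
    cur[I_KS] = i_ks
    cur[I_TO] = i_to
    cur[I_K1] = i_k1
    cur[I_F] = i_f
    cur[I_NACA] = i_naca
    cur[I_NAK] = i_nak
    cur[I_BNA] = i_bna
    cur[I_BCA] = i_bca
    cur[I_PCA] = i_pca
    cur[I_SEAL] = i_seal
    cur[I_TOTAL] = i_total

    # --- SR Ca2+ fluxes ---------------------------------------------------
    i_up = _VMAX_UP / (1.0 + (_K_UP / cai) ** 2)
    i_leak_sr = _V_LEAK_SR * (casr - cai)
    i_rel = (_A_REL * casr * casr / (_B_REL * _B_REL + casr * casr) + _C_REL) \
        * d * grel
    if cai < 0.00035:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    tau_g = 2.0

    # --- membrane equation ------------------------------------------------
    i_stim = 0.0
    if mode == MODE_CC and p[P_STIM_AMP] > 0.0:
        t_in = t % p[P_STIM_PERIOD]
        if t_in < p[P_STIM_DUR]:
            i_stim = p[P_STIM_AMP]

    if mode == MODE_CC:
        dy[0] = -(i_ion + i_seal) + i_stim
    elif mode == MODE_VC_RS:
        v_p = command_voltage(t, v0, v1, t0, dur) + v_ljp
        dy[0] = (v_p - v) / (ru_gohm * p[P_CM]) - i_ion - i_seal
    else:
        dy[0] = 0.0

    # --- ionic concentration balance -------------------------------------
    cm_f_vc = p[P_CM] / (F_SI * 1.0e-3 * p[P_VC])  # -> mM/ms per A/F
    buf_c = 1.0 / (1.0 + _BUF_C * _K_BUF_C / ((cai + _K_BUF_C) ** 2))
    buf_sr = 1.0 / (1.0 + _BUF_SR * _K_BUF_SR / ((casr + _K_BUF_SR) ** 2))
    dy[1] = buf_c * (i_leak_sr - i_up + i_rel
                     - (i_cal + i_cat + i_bca + i_pca - 2.0 * i_naca)
                     * cm_f_vc / 2.0)
    dy[2] = buf_sr * (p[P_VC] / p[P_VSR]) * (i_up - i_leak_sr - i_rel)
    if p[P_FIX_CONC] == 1.0:
        dy[3] = 0.0
        dy[4] = 0.0
    else:
        dy[3] = -(i_na + i_bna + i_f_na + 3.0 * i_nak + 3.0 * i_naca) * cm_f_vc
        dy[4] = -(i_k1 + i_to + i_kr + i_ks + i_f_k - 2.0 * i_nak - i_stim) \
            * cm_f_vc

    # --- gates ------------------------------------------------------------
    dy[5] = (m_inf - m) / tau_m
    dy[6] = (h_inf - h) / tau_h
    dy[7] = (j_inf - jg) / tau_j
    dy[8] = (d_inf - d) / tau_d
    dy[9] = (f_inf - f) / tau_f
    if fca_inf > fca and v > -60.0:
        dy[10] = 0.0
    else:
        dy[10] = (fca_inf - fca) / tau_fca
    if g_inf > grel and v > -60.0:
        dy[11] = 0.0
    else:
        dy[11] = (g_inf - grel) / tau_g
    dy[12] = (xr1_inf - xr1) / tau_xr1
    dy[13] = (xr2_inf - xr2) / tau_xr2
    dy[14] = (xs_inf - xs) / tau_xs
    dy[15] = (xf_inf - xf) / tau_xf
    dy[16] = (r_inf - rto) / tau_r
    dy[17] = (s_inf - sto) / tau_s
    dy[18] = (dt_inf - dt_g) / tau_dt
    dy[19] = (ft_inf - ft_g) / tau_ft

    return dy, cur


@njit(cache=True)
def rhs_only(t, y, p, mode, v0, v1, t0, dur, ru_gohm, v_ljp):
    dy, _ = compute(t, y, p, mode, v0, v1, t0, dur, ru_gohm, v_ljp)
    return dy


@njit(cache=True)
def currents_along(ts, ys, p, mode, v0s, v1s, t0s, durs, seg_idx, ru_gohm, v_ljp):
    """Recompute the named current densities at every stored sample.

    ``seg_idx[k]`` gives the protocol segment active at sample ``k`` (only
    used for the imposed-voltage clamp mode).
    """
    n = ts.shape[0]
    out = np.empty((n, NCURRENT))
    for k in range(n):
        i = seg_idx[k]
        _, cur = compute(ts[k], ys[k], p, mode,
                         v0s[i], v1s[i], t0s[i], durs[i], ru_gohm, v_ljp)
        out[k] = cur
    return out
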