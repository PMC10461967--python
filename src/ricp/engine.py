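"""Numerical integration of the iPSC-CM model under current and voltage clamp.

The stiff ODE system is integrated with LSODA at tight tolerances
(rtol = atol = 1e-8 by default; the fast Na+ activation gate demands them).
Voltage-clamp runs are integrated segment by segment so that command
discontinuities coincide exactly with solver restarts; a 1 ms step cap
preserves the protocol edges.  Current-clamp runs have no edges and use
adaptive steps.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import _core
from .artifact import ArtifactParameters
from .models import (ModelParameters, default_state, pack_parameters,
                     seed_state)
from .protocol import VCProtocol
from .trace import Trace


class SimulationError(RuntimeError):
    """Raised when the solver fails; carries the time of failure."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


def _check(sol, context: str):
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(
            f"{context}: solver failed at t={t_fail} ms: {sol.message}",
            t_fail)


def simulate_cc(params: ModelParameters,
                artifact: ArtifactParameters | None = None,
                duration: float = 10_000.0,
                dt: float = 0.5,
                stim_amp: float = 0.0,
                stim_period: float = 1000.0,
                stim_dur: float = 5.0,
                y0: np.ndarray | None = None,
                rtol: float = 1e-8,
                atol: float = 1e-8,
                max_step: float = np.inf) -> Trace:
    """Current-clamp simulation; returns the membrane-potential trace (mV).

    The membrane equation includes the seal-leak current for the artifact's
    R_seal (scaled by the model's I_leak multiplier); access resistance and
    junction offset do not apply in current clamp (perforated patch).
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    r_seal = artifact.R_seal if artifact is not None else np.inf
    p = pack_parameters(params, r_seal_gohm=r_seal, stim_amp=stim_amp,
                        stim_period=stim_period, stim_dur=stim_dur)
    if y0 is None:
        y0 = default_state(params.model_id)
    t_eval = np.arange(0.0, duration + dt / 2.0, dt)
    if t_eval[-1] > duration:
        t_eval = t_eval[:-1]
    if t_eval[-1] < duration:
        t_eval = np.append(t_eval, duration)

    def fun(t, y):
        return _core.rhs_only(t, y, p, _core.MODE_CC,
                              0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    sol = solve_ivp(fun, (0.0, duration), np.asarray(y0, dtype=float),
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
                    max_step=max_step)
    _check(sol, "current clamp")
    return Trace(sol.t, sol.y[0], "mV")


def simulate_vc(params: ModelParameters,
                artifact: ArtifactParameters,
                protocol: VCProtocol,
                dt: float = 0.5,
                y0: np.ndarray | None = None,
                rtol: float = 1e-8,
                atol: float = 1e-8,
                max_step: float = 1.0,
                return_full: bool = False):
    """Voltage-clamp simulation of a protocol; returns the recorded current.

    The recorded current I_out (A/F, capacitance-normalised) contains the
    ionic plus seal-leak current; with supercharging off it is the pipette
    current through the residual access resistance, which additionally
    carries the membrane capacitive transient.  With ``return_full`` the
    membrane-potential trace and the per-sample named current densities are
    returned as well.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    p = pack_parameters(params, r_seal_gohm=artifact.R_seal,
                        c_m=artifact.C_m)
    ru = artifact.R_residual_gohm
    ideal = ru <= 1.0e-12
    mode = _core.MODE_VC_IDEAL if ideal else _core.MODE_VC_RS
    v_ljp = artifact.V_ljp
    divider = artifact.divider

    segs = protocol.segments
    v0s = np.array([s.v_start for s in segs])
    v1s = np.array([s.v_end for s in segs])
    t0s = protocol.t_starts[:-1].copy()
    durs = np.array([s.duration for s in segs])
    total = protocol.total_duration

    t_grid = np.arange(0.0, total + dt / 2.0, dt)
    if t_grid[-1] > total:
        t_grid = t_grid[:-1]
    n = t_grid.size
    ys = np.empty((n, _core.NSTATE))
    seg_idx = np.empty(n, dtype=np.int64)

    y = np.asarray(default_state(params.model_id) if y0 is None else y0,
                   dtype=float).copy()
    if ideal:
        y[0] = v0s[0] + v_ljp
    else:
        y[0] = divider * (v0s[0] + v_ljp)

    pos = 0
    for i in range(len(segs)):
        t_a, t_b = t0s[i], t0s[i] + durs[i]
        if not ideal and artifact.supercharging:
            v_prev_end = v1s[i - 1] if i > 0 else v0s[0]
            if i == 0 or v0s[i] != v_prev_end:
                # idealised supercharge: membrane reaches the step target
                # (divider-corrected) within one sample of the edge
                y[0] = divider * (v0s[i] + v_ljp)
        k_hi = np.searchsorted(t_grid, t_b - 1e-9)
        t_eval = t_grid[pos:k_hi]
        if i == len(segs) - 1 and t_grid[-1] >= t_b - 1e-9:
            t_eval = t_grid[pos:]
            k_hi = n
        pts = np.append(t_eval, t_b) if (t_eval.size == 0 or
                                         t_eval[-1] < t_b) else t_eval

        def fun(t, yy, i=i):
            return _core.rhs_only(t, yy, p, mode, v0s[i], v1s[i],
                                  t0s[i], durs[i], ru, v_ljp)

        sol = solve_ivp(fun, (t_a, t_b), y, method="LSODA", t_eval=pts,
                        rtol=rtol, atol=atol, max_step=max_step)
        _check(sol, f"voltage clamp segment {i}")
        m = t_eval.size
        ys[pos:pos + m] = sol.y[:, :m].T
        seg_idx[pos:pos + m] = i
        pos += m
        y = sol.y[:, -1].copy()
    assert pos == n

    if ideal:
        v_m = np.array([_core.command_voltage(t_grid[k], v0s[seg_idx[k]],
                                              v1s[seg_idx[k]], t0s[seg_idx[k]],
                                              durs[seg_idx[k]]) + v_ljp
                        for k in range(n)])
        ys[:, 0] = v_m
    else:
        v_m = ys[:, 0]

    cur = _core.currents_along(t_grid, ys, p, mode, v0s, v1s, t0s, durs,
                               seg_idx, ru, v_ljp)
    if ideal or artifact.supercharging:
        i_out = cur[:, _core.I_TOTAL]
    else:
        v_p = np.array([_core.command_voltage(t_grid[k], v0s[seg_idx[k]],
                                              v1s[seg_idx[k]], t0s[seg_idx[k]],
                                              durs[seg_idx[k]]) + v_ljp
                        for k in range(n)])
        i_out = (v_p - v_m) / (ru * artifact.C_m)

    trace = Trace(t_grid, i_out, "A/F")
    if return_full:
        return trace, Trace(t_grid, v_m, "mV"), cur
    return trace


def init_steady_state(params: ModelParameters,
                      mode: str = "spontaneous",
                      duration_s: float = 1000.0,
                      r_seal_gohm: float = np.inf,
                      stim_amp: float = 10.0,
                      rtol: float = 1e-8,
                      atol: float = 1e-8) -> np.ndarray:
    """Find the baseline state by long current-clamp integration.

    Integrates the model with *dynamic* intracellular Na+/K+ for
    ``duration_s`` seconds (spontaneous, or paced at 1 Hz with 5 ms
    stimuli), stores the final [Na+]i/[K+]i into ``params`` as the fixed
    concentrations, and returns the final state.  The run is leak-free by
    default: the non-selective seal-leak current carries no Na+/K+, so
    including it in a dynamic-concentration run breaks the ionic charge
    balance; the fixed concentrations are the model's intrinsic baseline.
    """
    if mode not in ("spontaneous", "paced"):
        raise ValueError("mode must be 'spontaneous' or 'paced'")
    amp = stim_amp if mode == "paced" else 0.0
    p = pack_parameters(params, r_seal_gohm=r_seal_gohm, stim_amp=amp,
                        stim_period=1000.0, stim_dur=5.0,
                        fix_concentrations=False)
    y0 = seed_state(params.model_id)
    t_end = duration_s * 1000.0

    def fun(t, y):
        return _core.rhs_only(t, y, p, _core.MODE_CC,
                              0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    sol = solve_ivp(fun, (0.0, t_end), y0, method="LSODA",
                    t_eval=[t_end], rtol=rtol, atol=atol)
    _check(sol, "initialisation")
    y_end = sol.y[:, -1].copy()
    params.Na_i_fixed = float(y_end[3])
    params.K_i_fixed = float(y_end[4])
    return y_end
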