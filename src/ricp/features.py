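"""Feature extraction from voltage-clamp and current-clamp traces.

Voltage-clamp features are the minimum or arithmetic mean of the recorded
current over a 2 ms window centered at each labeled time point (both window
boundaries inclusive).  Current-clamp (action potential) features follow
the conventions used for heterogeneous iPSC-CM recordings:

* an AP event is an upward crossing of dV/dt >= 2 V/s followed within
  50 ms by a peak at least 30 mV above the preceding minimum — robust for
  slow, I_CaL-driven upstrokes;
* MP (maximal diastolic / minimal potential) is the mean of per-cycle
  minima, or the global minimum of a quiescent trace;
* APD90 is measured from the time of dV/dt_max to 90% repolarisation of
  the per-cycle amplitude (peak minus cycle minimum);
* CL is the interval between consecutive dV/dt_max times;
* features are averaged over all detected APs; coefficients of variation
  need at least three cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import TimePointSpec
from .trace import Trace

UPSTROKE_DVDT = 2.0      # V/s threshold for AP detection
PEAK_SEARCH_MS = 50.0    # look-ahead for the AP peak
MIN_AMPLITUDE = 30.0     # mV, peak above preceding minimum
REFRACTORY_MS = 100.0


def extract_vc_features(trace: Trace, specs: list) -> dict:
    """Per spec, the min or mean of samples with t in [t_center-1, t_center+1].

    Raises ``ValueError`` naming the spec if its window contains no samples.
    """
    if trace.units != "A/F":
        raise ValueError("VC feature extraction expects a current trace (A/F)")
    out = {}
    for spec in specs:
        half = spec.window / 2.0
        vals = trace.window(spec.t_center - half, spec.t_center + half)
        if vals.size == 0:
            raise ValueError(
                f"no samples in the {spec.label} window "
                f"[{spec.t_center - half}, {spec.t_center + half}] ms")
        out[spec.label] = float(np.min(vals) if spec.method == "min"
                                else np.mean(vals))
    return out


@dataclass
class APEvent:
    t_upstroke: float    # ms, dV/dt threshold crossing
    t_peak: float        # ms
    v_peak: float        # mV
    t_dvdt_max: float    # ms, within the upstroke
    dvdt_max: float      # V/s


@dataclass
class APFeatureSet:
    """AP features of one cell; absent features are None, never zero."""

    spontaneous: bool
    MP: float
    n_aps: int
    APD90: float | None = None
    CL: float | None = None
    dVdt_max: float | None = None
    CoV_CL: float | None = None
    CoV_APD90: float | None = None
    CoV_dVdt: float | None = None

    def to_dict(self) -> dict:
        return {
            "spontaneous": self.spontaneous, "MP": self.MP,
            "n_aps": self.n_aps, "APD90": self.APD90, "CL": self.CL,
            "dVdt_max": self.dVdt_max, "CoV_CL": self.CoV_CL,
            "CoV_APD90": self.CoV_APD90, "CoV_dVdt": self.CoV_dVdt,
        }


def _derivative(trace: Trace, smooth_ms: float = 1.0) -> np.ndarray:
    """dV/dt in mV/ms (= V/s) by central differences, with optional
    boxcar smoothing of the voltage over ~smooth_ms for noise robustness."""
    v = trace.value
    t = trace.t
    if smooth_ms > 0 and t.size > 4:
        dt = np.median(np.diff(t))
        w = max(int(round(smooth_ms / dt)), 1)
        if w > 1:
            kernel = np.ones(w) / w
            v = np.convolve(v, kernel, mode="same")
    return np.gradient(v, t)


def detect_aps(trace: Trace, smooth_ms: float = 1.0) -> list:
    """Detect AP events; a cell is spontaneous iff >= 1 event is found."""
    if trace.units != "mV":
        raise ValueError("AP detection expects a voltage trace (mV)")
    if trace.duration < 1000.0:
        raise ValueError("AP detection needs at least 1 s of data")
    t, v = trace.t, trace.value
    dvdt = _derivative(trace, smooth_ms)
    cross = np.flatnonzero((dvdt[1:] >= UPSTROKE_DVDT)
                           & (dvdt[:-1] < UPSTROKE_DVDT)) + 1
    events: list[APEvent] = []
    last_peak_idx = 0
    last_up_t = -np.inf
    for idx in cross:
        if t[idx] - last_up_t < REFRACTORY_MS:
            continue
        hi = np.searchsorted(t, t[idx] + PEAK_SEARCH_MS, side="right")
        if hi <= idx + 1:
            continue
        pk_rel = int(np.argmax(v[idx:hi]))
        pk = idx + pk_rel
        v_peak = v[pk]
        v_floor = float(np.min(v[last_peak_idx:idx + 1]))
        if v_peak - v_floor < MIN_AMPLITUDE:
            continue
        seg = slice(max(idx - 3, 0), pk + 1)
        k = int(np.argmax(dvdt[seg])) + seg.start
        events.append(APEvent(t[idx], t[pk], float(v_peak),
                              float(t[k]), float(dvdt[k])))
        last_peak_idx = pk
        last_up_t = t[idx]
    return events


def _cov(vals: list) -> float | None:
    if len(vals) < 3:
        return None
    arr = np.asarray(vals, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return float(arr.std(ddof=1) / abs(mean) * 100.0)


def ap_features(trace: Trace, smooth_ms: float = 1.0) -> APFeatureSet:
    """Compute the AP feature set of one current-clamp trace."""
    events = detect_aps(trace, smooth_ms)
    t, v = trace.t, trace.value
    if not events:
        return APFeatureSet(spontaneous=False, MP=float(np.min(v)), n_aps=0)

    # per-cycle diastolic minima: between each peak and the next upstroke
    mins = []
    for k, ev in enumerate(events):
        lo = np.searchsorted(t, ev.t_peak)
        hi = np.searchsorted(t, events[k + 1].t_upstroke) if k + 1 < len(events) \
            else t.size
        if hi - lo < 2 or (t[min(hi, t.size - 1)] - ev.t_peak) < 50.0:
            continue
        k_min = int(np.argmin(v[lo:hi]))
        if k + 1 == len(events) and (
                lo + k_min == t.size - 1
                or ev.v_peak - v[lo + k_min] < MIN_AMPLITUDE):
            # trace ends before the diastole of the last AP completes
            continue
        mins.append(float(v[lo + k_min]))
    mp = float(np.mean(mins)) if mins else float(np.min(v))

    # APD90 per cycle: dV/dt_max time to 90% repolarisation of the
    # per-cycle amplitude (peak - following diastolic minimum)
    apd90s = []
    for k, ev in enumerate(events):
        lo = np.searchsorted(t, ev.t_peak)
        hi = np.searchsorted(t, events[k + 1].t_upstroke) if k + 1 < len(events) \
            else t.size
        if hi - lo < 2:
            continue
        cyc_min = float(np.min(v[lo:hi]))
        v90 = ev.v_peak - 0.9 * (ev.v_peak - cyc_min)
        below = np.flatnonzero(v[lo:hi] <= v90)
        if below.size == 0:
            continue
        t90 = t[lo + below[0]]
        apd90s.append(float(t90 - ev.t_dvdt_max))
    cls = [b.t_dvdt_max - a.t_dvdt_max for a, b in zip(events, events[1:])]
    dvdts = [ev.dvdt_max for ev in events]

    return APFeatureSet(
        spontaneous=True,
        MP=mp,
        n_aps=len(events),
        APD90=float(np.mean(apd90s)) if apd90s else None,
        CL=float(np.mean(cls)) if cls else None,
        dVdt_max=float(np.mean(dvdts)) if dvdts else None,
        CoV_CL=_cov(cls),
        CoV_APD90=_cov(apd90s),
        CoV_dVdt=_cov(dvdts),
    )
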