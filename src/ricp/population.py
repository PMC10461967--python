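"""Population-of-models construction and sensitivity analysis.

A population is built by randomly scaling twelve ionic conductances
(I_Na, I_CaL, I_Kr, I_Ks, I_to, I_K1, I_f, I_leak, I_NaCa, I_NaK, I_bNa,
I_bCa) plus the cell capacitance C_m and the access resistance R_s between
0.25x and 4x their baseline values.  Each individual is run through the
full pipeline (voltage clamp + feature extraction, current clamp + AP
features) and Spearman rank correlations between parameters and the eight
current-isolating features quantify the sensitivity of each segment.

Scale factors are drawn log-uniformly by default (symmetric in fold change
around 1x); a uniform option is provided.  The sampled C_m and R_s scale
the measurement chain (voltage-clamp artifact model), while the ionic
model keeps its configured 45 pF capacitance.  The I_leak multiplier scales the
seal conductance 1/R_seal, so a 4x multiplier corresponds to a 0.5 GOhm
seal at the 2 GOhm baseline.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .artifact import ArtifactParameters
from .engine import SimulationError, simulate_cc, simulate_vc
from .features import ap_features
from .models import SAMPLED_CONDUCTANCES, ModelParameters
from .protocol import SEGMENT_LABELS, VCProtocol, ricp_protocol, ricp_timepoints
from .features import extract_vc_features

logger = logging.getLogger(__name__)

#: parameters sampled in the population, in table-column order
SAMPLED_PARAMETERS = tuple(SAMPLED_CONDUCTANCES) + ("C_m", "R_access")

AP_COLUMNS = ("MP", "APD90", "CL", "dVdt_max", "spontaneous", "n_aps")


@dataclass
class PopulationSpec:
    """Sampling specification for a population of in silico cells."""

    n: int = 500
    model_id: str = "kernik"
    seed: int = 0
    range: tuple = (0.25, 4.0)
    distribution: str = "log-uniform"   # or "uniform"
    baseline_artifact: ArtifactParameters = field(
        default_factory=ArtifactParameters)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        lo, hi = self.range
        if not (lo > 0 and hi >= lo):
            raise ValueError("range must satisfy 0 < lo <= hi")
        if self.distribution not in ("log-uniform", "uniform"):
            raise ValueError("distribution must be log-uniform or uniform")


def sample_population(spec: PopulationSpec) -> list:
    """Draw ``spec.n`` (ModelParameters, ArtifactParameters) pairs.

    Reproducible for a fixed seed; every sampled factor lies in
    ``spec.range``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.range
    pop = []
    base_art = spec.baseline_artifact
    for _ in range(spec.n):
        if spec.distribution == "log-uniform":
            factors = np.exp(rng.uniform(np.log(lo), np.log(hi),
                                         len(SAMPLED_PARAMETERS)))
        else:
            factors = rng.uniform(lo, hi, len(SAMPLED_PARAMETERS))
        named = dict(zip(SAMPLED_PARAMETERS, factors))
        mult = {k: named[k] for k in SAMPLED_CONDUCTANCES}
        # C_m and R_s scale the measurement chain: the ionic model keeps
        # the configured 45 pF cell
        params = ModelParameters(model_id=spec.model_id, multipliers=mult)
        art = dataclasses.replace(base_art,
                                  R_access=base_art.R_access * named["R_access"],
                                  C_m=45.0 * named["C_m"])
        pop.append((params, art))
    return pop


def run_cell(params: ModelParameters, artifact: ArtifactParameters,
             protocol: VCProtocol, cc_duration: float = 10_000.0,
             dt_vc: float = 0.5, dt_cc: float = 0.5,
             rtol: float = 1e-6, atol: float = 1e-8) -> dict:
    """Run the full RICP pipeline for one cell; returns one feature row."""
    vc = simulate_vc(params, artifact, protocol, dt=dt_vc,
                     rtol=rtol, atol=atol)
    feats = extract_vc_features(vc, ricp_timepoints())
    cc = simulate_cc(params, artifact, duration=cc_duration, dt=dt_cc,
                     rtol=rtol, atol=atol)
    ap = ap_features(cc)
    row = dict(feats)
    row.update(ap.to_dict())
    return row


def run_population(pop: list, protocol: VCProtocol | None = None,
                   cc_duration: float = 10_000.0,
                   rtol: float = 1e-6,
                   max_failure_frac: float = 0.2,
                   progress: bool = False) -> pd.DataFrame:
    """Run the pipeline on every individual and assemble the feature table.

    Failed integrations are logged and flagged (``failed`` column), not
    silently dropped; more than ``max_failure_frac`` failures aborts.
    """
    if not pop:
        raise ValueError("population is empty")
    if protocol is None:
        protocol = ricp_protocol()
    rows = []
    n_fail = 0
    for i, (params, art) in enumerate(pop):
        t0 = time.perf_counter()
        base = {f"mult_{k}": params.multipliers[k]
                for k in SAMPLED_CONDUCTANCES}
        base["C_m"] = art.C_m
        base["R_access"] = art.R_access
        try:
            row = run_cell(params, art, protocol, cc_duration, rtol=rtol)
            row["failed"] = False
        except SimulationError as exc:
            logger.warning("cell %d failed: %s", i, exc)
            n_fail += 1
            row = {lab: np.nan for lab in SEGMENT_LABELS}
            row.update({c: np.nan for c in AP_COLUMNS})
            row["failed"] = True
        row.update(base)
        row["cell"] = i
        rows.append(row)
        if progress:
            logger.info("cell %d/%d done in %.2f s", i + 1, len(pop),
                        time.perf_counter() - t0)
        if n_fail > max_failure_frac * len(pop):
            raise RuntimeError(
                f"{n_fail} of {i + 1} simulations failed "
                f"(> {max_failure_frac:.0%} of the population)")
    df = pd.DataFrame(rows).set_index("cell")
    return df


def spearman_sensitivity(table: pd.DataFrame,
                         features: list | None = None,
                         params: list | None = None) -> pd.DataFrame:
    """Spearman rho for every (parameter, feature) pair.

    Absent values are excluded pairwise; constant columns yield NaN.
    Requires at least 10 usable rows.
    """
    if features is None:
        features = list(SEGMENT_LABELS)
    if params is None:
        params = [f"mult_{k}" for k in SAMPLED_CONDUCTANCES] \
            + ["C_m", "R_access"]
    if len(table) < 10:
        raise ValueError("sensitivity analysis needs >= 10 rows")
    out = pd.DataFrame(index=params, columns=features, dtype=float)
    for pcol in params:
        for fcol in features:
            x = pd.to_numeric(table[pcol], errors="coerce")
            y = pd.to_numeric(table[fcol], errors="coerce")
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                out.loc[pcol, fcol] = np.nan
                continue
            rho = stats.spearmanr(x[ok], y[ok]).statistic
            out.loc[pcol, fcol] = rho
    return out


def trace_envelope(traces) -> tuple:
    """Pointwise (min, max) envelope of a list of equally sampled traces."""
    if not traces:
        raise ValueError("need at least one trace")
    vals = np.vstack([tr.value for tr in traces])
    return vals.min(axis=0), vals.max(axis=0)


def outside_population_range(value, population_values) -> bool:
    """Flag a measured value that falls outside the population's range.

    Used to compare a recorded feature (e.g. the current at the I_6mV time
    point) against the span of an in silico population; values above the
    maximum or below the minimum indicate dynamics the model population
    does not produce.
    """
    arr = np.asarray(population_values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("population values are all absent")
    return bool(value < arr.min() or value > arr.max())


def gkr_scan(scales=None,
             artifact: ArtifactParameters | None = None,
             model_id: str = "kernik",
             cc_duration: float = 10_000.0,
             rtol: float = 1e-6) -> pd.DataFrame:
    """Scan the I_Kr conductance and report the resulting MP.

    Default grid spans 0.1x to 1.6x of the baseline g_Kr (0.218025 nS/pF
    for the kernik profile) with the 2 GOhm baseline seal.  Solver
    failures at a scale are recorded and the scan continues.
    """
    if scales is None:
        scales = np.linspace(0.1, 1.6, 16)
    if artifact is None:
        artifact = ArtifactParameters()
    rows = []
    for s in scales:
        if not s > 0:
            raise ValueError("g_Kr scales must be > 0")
        params = ModelParameters(model_id=model_id,
                                 multipliers={"I_Kr": float(s)})
        try:
            cc = simulate_cc(params, artifact, duration=cc_duration,
                             rtol=rtol)
            ap = ap_features(cc)
            rows.append({"g_Kr_scale": float(s),
                         "g_Kr_nS_per_pF": float(s) * params.g_Kr_base,
                         "MP": ap.MP, "spontaneous": ap.spontaneous,
                         "failed": False})
        except SimulationError as exc:
            logger.warning("g_Kr scan failed at %.3gx: %s", s, exc)
            rows.append({"g_Kr_scale": float(s),
                         "g_Kr_nS_per_pF": float(s) * 0.218025,
                         "MP": np.nan, "spontaneous": False, "failed": True})
    return pd.DataFrame(rows)
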