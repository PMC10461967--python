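"""Synthetic stand-in for the 39-cell experimental iPSC-CM dataset.

Every downstream stage of the pipeline (feature extraction, correlation
screens, population comparisons) is testable without any recording by
generating a cohort of heterogeneous in silico cells: conductances scaled
log-uniformly in [0.25, 4]x, per-cell seal resistance (log-uniform over
1-10 GOhm by default — the experimental seal distribution beyond the
>300 MOhm pre-rupture criterion is unknown, so this is a documented
assumption), capacitance uniform over the experimental 18-98 pF range,
additive white Gaussian noise on the recorded current, and optionally one
long-APD outlier constructed by scaling down the repolarising K+ currents
(I_K1, I_f, I_Ks <= 0.3x).  All traces are mechanistic simulations; the
cohort emulates the heterogeneity of the recordings, not any specific
cell.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .artifact import ArtifactParameters
from .engine import SimulationError, simulate_cc, simulate_vc
from .features import ap_features, extract_vc_features
from .models import SAMPLED_CONDUCTANCES, ModelParameters
from .protocol import SEGMENT_LABELS, ricp_protocol, ricp_timepoints
from .trace import Trace

logger = logging.getLogger(__name__)


@dataclass
class CohortSpec:
    n_cells: int = 39
    seed: int = 0
    model_id: str = "kernik"
    conductance_range: tuple = (0.25, 4.0)
    r_seal_range_gohm: tuple = (1.0, 10.0)
    c_m_range_pf: tuple = (18.0, 98.0)
    noise_sd: float = 0.5          # A/F, additive white Gaussian on I_out
    outlier: bool = True
    cc_duration: float = 10_000.0
    dt: float = 0.5                # ms sampling, VC and CC

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass
class Cell:
    index: int
    params: ModelParameters
    artifact: ArtifactParameters
    vc: Trace                     # noisy recorded current, A/F
    cc: Trace                     # membrane potential, mV
    vc_features: dict
    ap: object          # APFeatureSet | None
    is_outlier: bool = False
    failed: bool = False

    def truth(self) -> dict:
        return {
            "model": self.params.to_dict(),
            "artifact": self.artifact.to_dict(),
            "is_outlier": self.is_outlier,
            "failed": self.failed,
        }


def _draw_cell_params(rng, spec: CohortSpec):
    lo, hi = spec.conductance_range
    mult = {k: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for k in SAMPLED_CONDUCTANCES}
    cm = float(rng.uniform(*spec.c_m_range_pf))
    r_seal = float(np.exp(rng.uniform(np.log(spec.r_seal_range_gohm[0]),
                                      np.log(spec.r_seal_range_gohm[1]))))
    params = ModelParameters(model_id=spec.model_id, multipliers=mult, C_m=cm)
    art = ArtifactParameters(R_seal=r_seal, C_m=cm)
    return params, art


def _simulate_cell(idx, params, art, spec, protocol, rng) -> Cell:
    vc_clean = simulate_vc(params, art, protocol, dt=spec.dt, rtol=1e-6)
    noise = rng.normal(0.0, spec.noise_sd, vc_clean.value.size) \
        if spec.noise_sd > 0 else 0.0
    vc = Trace(vc_clean.t, vc_clean.value + noise, "A/F")
    cc = simulate_cc(params, art, duration=spec.cc_duration, dt=spec.dt,
                     rtol=1e-6)
    feats = extract_vc_features(vc, ricp_timepoints())
    ap = ap_features(cc)
    return Cell(idx, params, art, vc, cc, feats, ap)


def generate_cohort(spec: CohortSpec, outdir=None) -> list:
    """Simulate a synthetic cohort; optionally write it to disk.

    Integration failures are resampled up to 5x per cell, then flagged.
    With ``outlier`` on, one cell receives I_K1/I_f/I_Ks multipliers drawn
    from [0.1, 0.3] to mirror a long-APD outlier with the smallest
    repolarising currents; its construction is re-drawn (up to 5x) until
    its APD90 exceeds twice the cohort median.
    """
    rng = np.random.default_rng(spec.seed)
    protocol = ricp_protocol()
    cells = []
    for i in range(spec.n_cells):
        for attempt in range(6):
            params, art = _draw_cell_params(rng, spec)
            try:
                cell = _simulate_cell(i, params, art, spec, protocol, rng)
                break
            except SimulationError as exc:
                logger.warning("cell %d attempt %d failed: %s",
                               i, attempt, exc)
        else:
            cell = Cell(i, params, art, None, None, {}, None, failed=True)
        cells.append(cell)

    if spec.outlier and spec.n_cells >= 2:
        idx = int(rng.integers(0, spec.n_cells))
        med = _median_apd90(cells)
        for attempt in range(5):
            params, art = _draw_cell_params(rng, spec)
            for k in ("I_K1", "I_f", "I_Ks"):
                params.multipliers[k] = float(rng.uniform(0.1, 0.3))
            try:
                cell = _simulate_cell(idx, params, art, spec, protocol, rng)
            except SimulationError:
                continue
            cell.is_outlier = True
            apd = cell.ap.APD90 if cell.ap is not None else None
            if med is None or (apd is not None and apd > 2.0 * med):
                cells[idx] = cell
                break
        else:
            logger.warning("outlier construction did not reach 2x median "
                           "APD90; keeping last attempt")
            cells[idx] = cell

    if outdir is not None:
        _write_cohort(cells, spec, Path(outdir))
    return cells


def _median_apd90(cells) -> float | None:
    vals = [c.ap.APD90 for c in cells
            if c.ap is not None and c.ap.APD90 is not None]
    return float(np.median(vals)) if vals else None


def _write_cohort(cells, spec, outdir: Path) -> None:
    from .io import write_trace
    outdir.mkdir(parents=True, exist_ok=True)
    for c in cells:
        d = outdir / f"cell_{c.index:03d}"
        d.mkdir(exist_ok=True)
        if not c.failed:
            write_trace(d / "vc.csv", c.vc)
            write_trace(d / "cc.csv", c.cc)
        with open(d / "truth.json", "w") as fh:
            json.dump(c.truth(), fh, indent=1)
    manifest = {"spec": dataclasses.asdict(spec), "n_cells": len(cells),
                "failed": [c.index for c in cells if c.failed]}
    manifest["spec"]["conductance_range"] = list(spec.conductance_range)
    manifest["spec"]["r_seal_range_gohm"] = list(spec.r_seal_range_gohm)
    manifest["spec"]["c_m_range_pf"] = list(spec.c_m_range_pf)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def cohort_table(cells) -> pd.DataFrame:
    """Feature table (VC features, AP features, ground-truth multipliers)."""
    rows = []
    for c in cells:
        row = {"cell": c.index, "failed": c.failed,
               "is_outlier": c.is_outlier}
        if not c.failed:
            row.update(c.vc_features)
            row.update(c.ap.to_dict())
            for k in SAMPLED_CONDUCTANCES:
                row[f"mult_{k}"] = c.params.multipliers[k]
            row["C_m"] = c.params.C_m
            row["R_seal"] = c.artifact.R_seal
        else:
            row.update({lab: np.nan for lab in SEGMENT_LABELS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell")


def cohort_report(cells) -> pd.DataFrame:
    """Summary statistics: mean, SD and mean per-cell CoV per AP feature."""
    tab = cohort_table(cells)
    ok = tab[~tab["failed"]]
    if not ok["spontaneous"].any():
        raise ValueError("cohort report needs at least one spontaneous cell")
    rows = {}
    for feat, cov_col in (("MP", None), ("APD90", "CoV_APD90"),
                          ("CL", "CoV_CL"), ("dVdt_max", "CoV_dVdt")):
        vals = pd.to_numeric(ok[feat], errors="coerce").dropna()
        cov = np.nan
        if cov_col is not None and cov_col in ok:
            covs = pd.to_numeric(ok[cov_col], errors="coerce").dropna()
            cov = float(covs.mean()) if covs.size else np.nan
        rows[feat] = {"mean": float(vals.mean()) if vals.size else np.nan,
                      "SD": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                      "CoV_mean": cov}
    return pd.DataFrame(rows).T[["mean", "SD", "CoV_mean"]]
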