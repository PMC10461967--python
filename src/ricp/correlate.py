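"""Correlation of current-isolating segment features with AP features.

Each of the eight segments is screened against one AP feature at a time
with a Spearman rank correlation (average ranks for ties, p-value from the
t-distribution approximation) and an ordinary least-squares regression.
Per-segment significance is reported at p < .05 without multiple-testing
correction, matching standard per-segment reporting; a Benjamini-Hochberg
option is available.  Quiescent cells carry only MP, so they drop out of
APD90/CL/dV/dt screens pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import SEGMENT_LABELS


@dataclass
class CorrelationResult:
    segment: str
    ap_feature: str
    rho: float
    p_value: float
    slope: float
    intercept: float
    n: int
    significant: bool
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "segment": self.segment, "ap_feature": self.ap_feature,
            "rho": self.rho, "p_value": self.p_value, "slope": self.slope,
            "intercept": self.intercept, "n": self.n,
            "significant": self.significant, "defined": self.defined,
        }


def correlate(x, y, segment: str = "x", ap_feature: str = "y",
              alpha: float = 0.05) -> CorrelationResult:
    """Spearman rho + p and OLS slope/intercept for one pair of variables.

    Non-finite values are dropped pairwise; n >= 3 after dropping is
    required.  All-constant input yields an undefined (flagged) result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired values, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(segment, ap_feature, np.nan, np.nan,
                                 np.nan, np.nan, n, False, defined=False)
    sp = stats.spearmanr(x, y)
    ols = stats.linregress(x, y)
    p = float(sp.pvalue)
    return CorrelationResult(segment, ap_feature, float(sp.statistic), p,
                             float(ols.slope), float(ols.intercept), n,
                             bool(p < alpha))


def segment_ap_screen(table: pd.DataFrame, ap_feature: str,
                      subset=None, alpha: float = 0.05,
                      benjamini_hochberg: bool = False) -> list:
    """Correlate every segment feature against one AP feature.

    ``subset`` is an optional boolean predicate on the table rows (e.g.
    ``lambda df: df["MP"] > -70``) applied before correlating.  Segments
    whose subset leaves fewer than 3 pairs are flagged, not computed.
    """
    missing = [s for s in SEGMENT_LABELS if s not in table.columns]
    if missing:
        raise ValueError(f"table is missing segment columns: {missing}")
    if ap_feature not in table.columns:
        raise ValueError(f"table has no column {ap_feature!r}")
    df = table
    if subset is not None:
        df = df[subset(df).fillna(False)] if hasattr(subset(df), "fillna") \
            else df[subset(df)]
    results = []
    for seg in SEGMENT_LABELS:
        x = pd.to_numeric(df[seg], errors="coerce").to_numpy()
        y = pd.to_numeric(df[ap_feature], errors="coerce").to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            results.append(CorrelationResult(seg, ap_feature, np.nan, np.nan,
                                             np.nan, np.nan, int(ok.sum()),
                                             False, defined=False))
            continue
        results.append(correlate(x[ok], y[ok], seg, ap_feature, alpha))
    if benjamini_hochberg:
        defined = [r for r in results if r.defined]
        ps = np.array([r.p_value for r in defined])
        order = np.argsort(ps)
        m = len(ps)
        thresh = np.zeros(m, dtype=bool)
        max_k = 0
        for rank, idx in enumerate(order, start=1):
            if ps[idx] <= alpha * rank / m:
                max_k = rank
        for rank, idx in enumerate(order, start=1):
            thresh[idx] = rank <= max_k
        for r, sig in zip(defined, thresh):
            r.significant = bool(sig)
    return results


def screen_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
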