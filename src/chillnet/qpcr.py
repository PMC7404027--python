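"""Relative qPCR quantification (2^-ddCt) and RNA-seq concordance.

Per sample, dCt = Ct_target - Ct_reference removes loading differences
via the reference gene; ddCt = dCt - mean(dCt over the control
condition) anchors the scale at the control, and the relative quantity
RQ = 2^-ddCt expresses fold change versus control. By construction the
geometric mean of control-condition RQs is 1.

Concordance between platforms is the Pearson correlation (with
two-sided Student-t p, df = n - 2) and least-squares slope of paired
log2 fold changes.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .network import correlation_pvalue

__all__ = ["ddct", "concordance", "ConcordanceResult"]

REQUIRED_COLUMNS = ("gene", "sample", "condition", "ct_target", "ct_reference")


def ddct(ct_table: pd.DataFrame, control: str) -> pd.DataFrame:
    """2^-ddCt relative quantification against a control condition.

    ``ct_table`` columns: gene, sample, condition, ct_target,
    ct_reference. The per-gene baseline is the mean dCt over the control
    condition's replicates. Returns the table with dct, ddct and rq
    columns appended.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    t = ct_table.copy()
    for col in ("ct_target", "ct_reference"):
        vals = t[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError(f"{col} must be finite and positive")
    t["dct"] = t["ct_target"] - t["ct_reference"]
    out = []
    for gene, grp in t.groupby("gene", sort=False):
        ctrl = grp.loc[grp["condition"] == control, "dct"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no control condition {control!r}")
        baseline = float(ctrl.mean())
        g = grp.copy()
        g["ddct"] = g["dct"] - baseline
        g["rq"] = np.power(2.0, -g["ddct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


class ConcordanceResult(NamedTuple):
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def concordance(rnaseq_log2fc, qpcr_log2fc) -> ConcordanceResult:
    """Pearson correlation and regression slope of paired log2 fold changes."""
    x = np.asarray(rnaseq_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired fold-change vectors must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need >= 3 paired fold changes")
    fit = stats.linregress(x, y)
    r = float(np.clip(fit.rvalue, -1.0, 1.0))
    return ConcordanceResult(
        r=r,
        p=correlation_pvalue(r, x.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )
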