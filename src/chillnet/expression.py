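"""Expression-matrix QC, filtering, sample correlation and DE gating.

The pipeline's central object is a genes x samples matrix of nonnegative
FPKM-scale abundances, held as a pandas DataFrame with gene ids in the
index and sample ids in the columns. Functions here implement the
pre-network stages: the expressed-gene filter (max FPKM >= 1), per-stage
expressed-set algebra, Pearson sample-sample correlation, the display
log-transform log10(FPKM + 0.01), and the differential-expression gate
(FDR < 0.05 and linear fold change >= 2).

The DE test is a two-sided t-test on log2(FPKM + 1) with
Benjamini-Hochberg adjustment. The default is the pooled-variance
Student t: with three replicates per group the Welch/Satterthwaite
degrees of freedom collapse to ~2 and the test loses most of its power,
so equal variances are assumed by default (``variant="welch"`` restores
the unpooled test). The negative-binomial machinery of count-based DE
callers is intentionally out of scope: the reproduced contract is the
FDR/fold-change gate, and the test statistic is a pluggable detail
behind it.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import SampleDesign

__all__ = [
    "validate_expression",
    "filter_expressed",
    "expressed_sets",
    "sample_correlation",
    "log_transform",
    "call_degs",
    "DifferentialExpression",
]

logger = logging.getLogger(__name__)

FOLD_CHANGE_PSEUDOCOUNT = 0.01  # mirrors the log10(FPKM + 0.01) display transform


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the FPKM matrix contract: unique ids, finite nonnegative values."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    return matrix


@dataclass
class ExpressedFilterResult:
    kept: pd.DataFrame          # genes passing the threshold
    expressed: set[str]         # max across samples >= threshold
    detected: set[str]          # max across samples > 0

    @property
    def n_kept(self) -> int:
        return self.kept.shape[0]


def filter_expressed(matrix: pd.DataFrame, threshold: float = 1.0) -> ExpressedFilterResult:
    """Keep genes whose maximum FPKM across samples is >= ``threshold``.

    The boundary is inclusive: a gene reaching exactly the threshold in a
    single sample is kept. Also reports the *detected* set (any nonzero
    signal), the looser notion used when counting transcripts with
    FPKM > 0.
    """
    validate_expression(matrix)
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    gene_max = matrix.max(axis=1)
    expressed = set(matrix.index[gene_max >= threshold])
    detected = set(matrix.index[gene_max > 0])
    kept = matrix.loc[gene_max >= threshold]
    logger.info("expressed filter: %d / %d genes kept at FPKM >= %g",
                kept.shape[0], matrix.shape[0], threshold)
    return ExpressedFilterResult(kept=kept, expressed=expressed, detected=detected)


@dataclass
class StageSetReport:
    sets: dict[str, set[str]]              # stage -> expressed genes
    pairwise: pd.DataFrame                 # intersection / difference sizes
    subset_flags: dict[tuple[str, str], bool]  # (a, b) -> a subset of b


def expressed_sets(
    matrix: pd.DataFrame,
    design: SampleDesign,
    threshold: float = 1.0,
) -> StageSetReport:
    """Per-stage expressed gene sets (replicate mean >= threshold) and their algebra."""
    validate_expression(matrix)
    design.check_covers(matrix.columns)
    sets: dict[str, set[str]] = {}
    for stage in design.stages:
        cols = design.samples_in_stage(stage)
        mean = matrix[cols].mean(axis=1)
        sets[stage] = set(matrix.index[mean >= threshold])
    rows = []
    flags = {}
    for a, b in itertools.permutations(sets, 2):
        flags[(a, b)] = sets[a] <= sets[b]
    for a, b in itertools.combinations(sets, 2):
        rows.append({
            "stage_a": a,
            "stage_b": b,
            "n_a": len(sets[a]),
            "n_b": len(sets[b]),
            "intersection": len(sets[a] & sets[b]),
            "only_a": len(sets[a] - sets[b]),
            "only_b": len(sets[b] - sets[a]),
        })
    return StageSetReport(sets=sets, pairwise=pd.DataFrame(rows), subset_flags=flags)


def sample_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of expression profiles.

    Zero-variance samples yield NaN entries (flagged, not fatal); their
    diagonal is still 1 by convention.
    """
    validate_expression(matrix)
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 genes for sample correlation")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0)
    degenerate = list(matrix.columns[sd == 0])
    if degenerate:
        logger.warning("zero-variance samples, correlation undefined: %s", degenerate)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


def log_transform(matrix: pd.DataFrame, pseudocount: float = 0.01) -> pd.DataFrame:
    """Elementwise log10(FPKM + pseudocount), the heatmap display scale."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative expression values")
    return pd.DataFrame(
        np.log10(values + pseudocount), index=matrix.index, columns=matrix.columns
    )


def _ttest_log2(group_a: np.ndarray, group_b: np.ndarray, variant: str) -> np.ndarray:
    """Vectorized two-sided t-test per gene on log2(FPKM + 1)."""
    if variant not in {"student", "welch"}:
        raise ValueError(f"unknown test variant {variant!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            np.log2(group_b + 1.0), np.log2(group_a + 1.0),
            axis=1, equal_var=(variant == "student"),
        )
    return np.asarray(res.pvalue, dtype=float)


def call_degs(
    matrix: pd.DataFrame,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    fold_change: float = 2.0,
    variant: str = "student",
) -> pd.DataFrame:
    """Differential expression between two stages with the FDR/FC gate.

    Per gene: two-sided t-test on log2(FPKM + 1) between replicate
    groups (pooled-variance Student by default, ``variant="welch"`` for
    unpooled), BH adjustment across tested genes, and a linear fold change
    FC = (mean_b + c) / (mean_a + c) with c = 0.01. Status is ``up`` when
    FDR < alpha and FC >= fold_change, ``down`` when FDR < alpha and
    FC <= 1/fold_change, else ``ns``. Genes with zero variance in both
    groups get p = 1 (logged), so constant genes can never be called.

    Returns a DataFrame with columns gene, log2fc, p, fdr, status.
    """
    validate_expression(matrix)
    cols_a = design.samples_in_stage(group_a)
    cols_b = design.samples_in_stage(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each stage needs >= 2 replicates for the DE test")
    a = matrix[cols_a].to_numpy(dtype=float)
    b = matrix[cols_b].to_numpy(dtype=float)

    p = _ttest_log2(a, b, variant)
    flat = np.isnan(p)
    if flat.any():
        logger.info("%d genes with zero variance in both groups: p set to 1", flat.sum())
        p = np.where(flat, 1.0, p)

    fdr = multipletests(p, method="fdr_bh")[1]
    c = FOLD_CHANGE_PSEUDOCOUNT
    fc = (b.mean(axis=1) + c) / (a.mean(axis=1) + c)
    log2fc = np.log2(fc)
    status = np.where(
        (fdr < alpha) & (fc >= fold_change), "up",
        np.where((fdr < alpha) & (fc <= 1.0 / fold_change), "down", "ns"),
    )
    out = pd.DataFrame({
        "gene": matrix.index,
        "log2fc": log2fc,
        "p": p,
        "fdr": fdr,
        "status": status,
    }).set_index("gene")
    logger.info("DEGs %s vs %s: %d up, %d down / %d tested",
                group_a, group_b, (status == "up").sum(), (status == "down").sum(),
                len(status))
    return out


def deg_union(
    matrix: pd.DataFrame,
    design: SampleDesign,
    alpha: float = 0.05,
    fold_change: float = 2.0,
) -> tuple[set[str], pd.DataFrame]:
    """Union of DEGs over all pairwise stage comparisons.

    This union is the gene universe handed to coexpression-network
    construction. Also returns the per-comparison up/down counts laid out
    one row per contrast.
    """
    union: set[str] = set()
    rows = []
    for a, b in itertools.combinations(design.stages, 2):
        table = call_degs(matrix, design, a, b, alpha=alpha, fold_change=fold_change)
        hits = table.index[table["status"] != "ns"]
        union.update(hits)
        rows.append({
            "comparison": f"{a}-vs-{b}",
            "up": int((table["status"] == "up").sum()),
            "down": int((table["status"] == "down").sum()),
            "total": int(len(hits)),
        })
    return union, pd.DataFrame(rows)


@dataclass
class DifferentialExpression:
    """Thin model wrapper: bind data once, run several contrasts.

    ``DifferentialExpression(matrix, design).fit("G1.T0", "G1.T3")``
    returns the gated DE table for that contrast.
    """

    matrix: pd.DataFrame
    design: SampleDesign
    alpha: float = 0.05
    fold_change: float = 2.0
    results_: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def fit(self, group_a: str, group_b: str) -> pd.DataFrame:
        table = call_degs(
            self.matrix, self.design, group_a, group_b,
            alpha=self.alpha, fold_change=self.fold_change,
        )
        self.results_[(group_a, group_b)] = table
        return table

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": f"{a}-vs-{b}",
                "up": int((t["status"] == "up").sum()),
                "down": int((t["status"] == "down").sum()),
            }
            for (a, b), t in self.results_.items()
        ]
        return pd.DataFrame(rows)
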