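"""Stage-specific hub-gene mining and thresholded network export.

Hub genes sit at the centre of a coexpression module and are
preferentially expressed at the module's peak ("preponderant") stage.
Three per-gene scores drive the selection:

* Z-score: stage means normalized across the gene universe within each
  stage, so genes highly expressed relative to the stage's distribution
  score high;
* SSC (stage specificity score): the share of a gene's summed stage
  means attributable to one stage; SSC near 1 means the gene is
  expressed in essentially one stage only;
* kME: module membership (from the network stage).

A gene is a hub of its module iff kME > 0.8 and SSC at the module's
preponderant stage > 0.5 (both strict). For display and graph export,
the top-N hubs ranked by Z-score at the peak stage are connected by
every TOM edge with weight strictly above the export threshold
(default 0.45).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import SampleDesign
from .network import ModulePartition, UNASSIGNED

__all__ = ["StageSummary", "stage_zscores", "ssc", "select_hubs",
           "EdgeList", "build_network"]

logger = logging.getLogger(__name__)


@dataclass
class StageSummary:
    """Per-gene stage means (over replicates) and stage-wise Z-scores."""

    means: pd.DataFrame    # genes x stages, FPKM scale
    zscores: pd.DataFrame  # genes x stages, normalized over the gene universe


def stage_zscores(
    matrix: pd.DataFrame,
    design: SampleDesign,
    universe: Iterable[str] | None = None,
) -> StageSummary:
    """Stage means and within-stage Z-scores over a gene universe.

    Z_{g,s} = (m_{g,s} - mu_s) / sigma_s with mu_s, sigma_s the mean and
    (sample) sd of the stage means over the universe. A stage where all
    universe genes have the same mean has zero dispersion and is an
    error.
    """
    universe = list(universe) if universe is not None else list(matrix.index)
    missing = [g for g in universe if g not in matrix.index]
    if missing:
        raise KeyError(f"universe genes absent from matrix: {missing[:10]}")
    design.check_covers(matrix.columns)
    sub = matrix.loc[universe]
    means = pd.DataFrame({
        stage: sub[design.samples_in_stage(stage)].mean(axis=1)
        for stage in design.stages
    })
    sigma = means.std(axis=0, ddof=1)
    if (sigma == 0).any():
        bad = list(sigma.index[sigma == 0])
        raise ValueError(f"zero dispersion in stage(s) {bad}: Z-score undefined")
    z = (means - means.mean(axis=0)) / sigma
    return StageSummary(means=means, zscores=z)


def ssc(summary: StageSummary) -> pd.DataFrame:
    """Stage specificity score: each stage's share of a gene's summed means.

    Rows sum to 1 for genes with nonzero total expression; all-zero
    genes are flagged NaN.
    """
    total = summary.means.sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.warning("%d all-zero genes: SSC undefined", int(zero.sum()))
    out = summary.means.div(total.where(~zero), axis=0)
    return out


def select_hubs(
    kme_table: pd.DataFrame,
    ssc_matrix: pd.DataFrame,
    partition: ModulePartition,
    preponderant_stage: Mapping[str, str],
    summary: StageSummary | None = None,
    kme_min: float = 0.8,
    ssc_min: float = 0.5,
) -> pd.DataFrame:
    """Hub table: per module gene scores and the hub flag.

    A gene is a hub of its own module iff its kME to that module exceeds
    ``kme_min`` AND its SSC at the module's preponderant stage exceeds
    ``ssc_min`` (strict inequalities). Genes with missing kME or SSC are
    skipped with a warning.
    """
    rows = []
    skipped = 0
    for gene, module in partition.labels.items():
        if module == UNASSIGNED or module not in kme_table.columns:
            continue
        stage = preponderant_stage[module]
        k = kme_table.at[gene, module] if gene in kme_table.index else np.nan
        s = ssc_matrix.at[gene, stage] if gene in ssc_matrix.index else np.nan
        if np.isnan(k) or np.isnan(s):
            skipped += 1
            continue
        z = np.nan
        if summary is not None and gene in summary.zscores.index:
            z = float(summary.zscores.at[gene, stage])
        rows.append({
            "gene": gene,
            "module": module,
            "stage": stage,
            "zscore": z,
            "kme": float(k),
            "ssc": float(s),
            "is_hub": bool(k > kme_min and s > ssc_min),
        })
    if skipped:
        logger.warning("skipped %d genes with missing kME/SSC", skipped)
    table = pd.DataFrame(
        rows, columns=["gene", "module", "stage", "zscore", "kme", "ssc", "is_hub"]
    ).set_index("gene")
    logger.info("hub selection: %d hubs / %d module genes",
                int(table["is_hub"].sum()), len(table))
    return table


@dataclass
class EdgeList:
    """Undirected thresholded network: edges (a < b) and node degrees."""

    edges: pd.DataFrame  # source, target, weight
    nodes: pd.DataFrame  # gene, degree

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_sum(self) -> int:
        return int(self.nodes["degree"].sum())


def build_network(
    tom_matrix: pd.DataFrame,
    nodes: Iterable[str],
    ranking: pd.Series | None = None,
    weight_min: float = 0.45,
    top_n: int = 100,
) -> EdgeList:
    """Export the top-N nodes and their strong TOM edges.

    Nodes are ranked by ``ranking`` (typically the Z-score at the
    module's preponderant stage) and the top ``top_n`` kept; every pair
    with TOM weight strictly above ``weight_min`` becomes an undirected
    edge in canonical (source < target) order. Node degree counts
    incident edges.
    """
    nodes = list(nodes)
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    missing = [g for g in nodes if g not in tom_matrix.index]
    if missing:
        raise KeyError(f"nodes absent from TOM: {missing[:10]}")
    if ranking is not None:
        nodes = sorted(nodes, key=lambda g: -float(ranking[g]))
    if top_n < len(nodes):
        nodes = nodes[:top_n]
    elif top_n > len(nodes):
        logger.warning("top_n=%d exceeds the %d available nodes: using all",
                       top_n, len(nodes))
    sub = tom_matrix.loc[nodes, nodes].to_numpy(dtype=float)
    order = np.array(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = sub[iu, ju] > weight_min
    pairs = [
        tuple(sorted((order[i], order[j]))) + (float(sub[i, j]),)
        for i, j in zip(iu[keep], ju[keep])
    ]
    edges = pd.DataFrame(pairs, columns=["source", "target", "weight"])
    degree = pd.Series(0, index=nodes, dtype=int)
    for a, b, _ in pairs:
        degree[a] += 1
        degree[b] += 1
    node_table = pd.DataFrame({"gene": nodes, "degree": degree.values})
    return EdgeList(edges=edges, nodes=node_table)
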