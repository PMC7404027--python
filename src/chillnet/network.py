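"""Weighted gene coexpression network analysis (WGCNA-style).

The network stage turns a genes x samples expression matrix into:

* a soft-thresholded adjacency  A_ij = |cor(x_i, x_j)|^beta  (unsigned;
  a signed variant ((1 + r)/2)^beta is available),
* the topological overlap matrix (TOM), which credits two genes both for
  their direct adjacency and for sharing neighbours:

      TOM_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij),
      l_ij = sum_{u != i,j} A_iu * A_uj,   k_i = sum_{j != i} A_ij,

* modules from average-linkage hierarchical clustering of 1 - TOM. The
  tree is cut by a deterministic height scan: every unique merge height
  is tried and the height producing the most clusters of size >=
  ``min_module_size`` wins (ties -> lowest height). Small clusters are
  left unassigned (the grey module of the classical workflow),
* a module eigengene (first right singular vector of the standardized
  member profiles, unit norm, sign aligned with the mean member
  profile), close modules merged when their eigengene dissimilarity
  1 - cor falls strictly below ``merge_cut_height``,
* kME (module membership): Pearson correlation of each gene with each
  module eigengene,
* module-sample and module-trait Pearson correlations with two-sided
  Student-t p-values at df = n - 2.

Model usage follows the fit/results idiom::

    model = CoexpressionNetwork(fpkm, design, power=12)
    res = model.fit()
    res.summary()
    res.module_sample_correlations()
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .design import SampleDesign
from .expression import validate_expression

__all__ = [
    "soft_adjacency",
    "tom",
    "detect_modules",
    "eigengene",
    "eigengene_matrix",
    "merge_modules",
    "kme",
    "module_correlations",
    "correlation_pvalue",
    "ModulePartition",
    "CoexpressionNetwork",
    "CoexpressionResults",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

def soft_adjacency(matrix: pd.DataFrame, beta: float = 12, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded coexpression adjacency.

    Unsigned: A_ij = |r_ij|^beta. Signed: A_ij = ((1 + r_ij)/2)^beta.
    Zero-variance genes get adjacency 0 to everything (flagged), and the
    diagonal is fixed at 1.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for gene-gene correlation")
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        logger.warning("%d zero-variance genes: adjacency set to 0: %s",
                       int((sd == 0).sum()),
                       list(matrix.index[sd == 0][:10]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(values)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -1.0, 1.0)
    adj = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.index)


def tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a soft adjacency.

    Vectorized via one matrix product: with unit diagonal,
    l_ij = (A @ A)_ij - 2 A_ij for i != j.
    """
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    n = a.shape[0]
    aa = a @ a
    shared = aa - 2.0 * a  # subtract the u = i and u = j terms (diag 1)
    k = a.sum(axis=1) - 1.0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (shared + a) / denom
    t[denom == 0] = 0.0
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Gene -> module labels plus the dendrogram that produced them."""

    labels: pd.Series                    # gene -> module label or "unassigned"
    min_module_size: int
    linkage_matrix: np.ndarray | None = None
    cut_height: float | None = None

    @property
    def modules(self) -> dict[str, list[str]]:
        """Module label -> member genes, excluding unassigned."""
        out: dict[str, list[str]] = {}
        for gene, lab in self.labels.items():
            if lab != UNASSIGNED:
                out.setdefault(lab, []).append(gene)
        return out

    @property
    def module_sizes(self) -> pd.Series:
        sizes = {m: len(g) for m, g in self.modules.items()}
        return pd.Series(sizes, dtype=int).sort_values(ascending=False)

    def relabel(self, mapping: Mapping[str, str]) -> "ModulePartition":
        labels = self.labels.map(lambda lab: mapping.get(lab, lab))
        return ModulePartition(labels, self.min_module_size,
                               self.linkage_matrix, self.cut_height)

    def to_newick(self) -> str:
        """Dendrogram as nested Newick text for external inspection."""
        if self.linkage_matrix is None:
            return "();"
        genes = list(self.labels.index)
        n = len(genes)
        nodes: dict[int, str] = {i: genes[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for idx, (left, right, h, _) in enumerate(self.linkage_matrix):
            left, right = int(left), int(right)
            bl = h - heights[left]
            br = h - heights[right]
            nodes[n + idx] = f"({nodes[left]}:{bl:.6g},{nodes[right]}:{br:.6g})"
            heights[n + idx] = h
        return nodes[n + len(self.linkage_matrix) - 1] + ";"


def _cluster_tree(dissimilarity: np.ndarray) -> np.ndarray:
    d = np.asarray(dissimilarity, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return linkage(squareform(d, checks=False), method="average")


def detect_modules(tom_matrix: pd.DataFrame, min_module_size: int = 50) -> ModulePartition:
    """Cut the average-linkage tree of 1 - TOM into modules.

    The cut height is chosen by scanning the tree's unique merge heights
    and keeping the height that maximizes the number of clusters with at
    least ``min_module_size`` members (ties -> lowest such height).
    Clusters below the size floor become "unassigned". Module labels are
    M1, M2, ... in decreasing size order.
    """
    genes = list(tom_matrix.index)
    n = len(genes)
    if n < 2:
        raise ValueError("need >= 2 genes to cluster")
    if n < min_module_size:
        logger.warning("only %d genes < min module size %d: all unassigned",
                       n, min_module_size)
        return ModulePartition(
            pd.Series(UNASSIGNED, index=genes), min_module_size)

    z = _cluster_tree(1.0 - tom_matrix.to_numpy(dtype=float))
    heights = np.unique(z[:, 2])
    best_h, best_count, best_assign = None, 0, None
    for h in heights:
        assign = fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(assign)
        count = int((sizes >= min_module_size).sum())
        if count > best_count:
            best_h, best_count, best_assign = float(h), count, assign
    if best_assign is None:
        logger.warning("no cut height yields a cluster of size >= %d", min_module_size)
        return ModulePartition(pd.Series(UNASSIGNED, index=genes),
                               min_module_size, z, None)

    sizes = pd.Series(best_assign).value_counts()
    big = sizes[sizes >= min_module_size].index
    # decreasing size order -> M1 is the largest module
    name_of = {cid: f"M{rank + 1}" for rank, cid in enumerate(big)}
    labels = pd.Series(
        [name_of.get(cid, UNASSIGNED) for cid in best_assign], index=genes)
    logger.info("tree cut at height %.4g: %d modules, %d unassigned",
                best_h, best_count, int((labels == UNASSIGNED).sum()))
    return ModulePartition(labels, min_module_size, z, best_h)


# ---------------------------------------------------------------------------
# eigengenes, merging, kME
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    z = np.zeros_like(x)
    np.divide(x - mean, sd, out=z, where=sd > 0)
    return z, keep


def eigengene(matrix: pd.DataFrame, members: Iterable[str]) -> tuple[pd.Series, float]:
    """Module eigengene and its explained-variance fraction.

    Member genes are standardized across samples; the eigengene is the
    first right singular vector (a unit-norm profile over samples), with
    its sign chosen so it is never anticorrelated with the mean
    standardized member profile. Constant genes are dropped with a
    warning.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module needs >= 2 member genes")
    sub = matrix.loc[members]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    z, keep = _standardize_rows(sub.to_numpy(dtype=float))
    if not keep.all():
        logger.warning("dropping %d constant genes from eigengene", int((~keep).sum()))
        z = z[keep]
    if z.shape[0] == 0:
        raise ValueError("all member genes constant")
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if float(e @ mean_profile) < 0:
        e = -e
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return pd.Series(e, index=matrix.columns, name="eigengene"), var_explained


def eigengene_matrix(
    matrix: pd.DataFrame, partition: ModulePartition
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes for every non-grey module (module x sample) + variance explained."""
    rows, varexp = {}, {}
    for module, members in partition.modules.items():
        e, v = eigengene(matrix, members)
        rows[module] = e
        varexp[module] = v
    if not rows:
        return pd.DataFrame(columns=matrix.columns), pd.Series(dtype=float)
    eig = pd.DataFrame(rows).T.loc[sorted(rows, key=lambda m: -len(partition.modules[m]))]
    return eig, pd.Series(varexp)


def merge_modules(
    matrix: pd.DataFrame,
    partition: ModulePartition,
    cut_height: float = 0.75,
) -> tuple[ModulePartition, pd.DataFrame]:
    """Merge modules whose eigengenes cluster strictly below ``cut_height``.

    Average-linkage clustering on 1 - cor(eigengene); groups joined at
    height < cut_height are unioned into the largest member's label; the
    procedure repeats until a fixpoint. Returns the merged partition and
    its recomputed eigengene matrix.
    """
    part = partition
    while True:
        modules = part.modules
        if len(modules) <= 1:
            break
        eig, _ = eigengene_matrix(matrix, part)
        corr = np.corrcoef(eig.to_numpy(dtype=float))
        corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
        z = _cluster_tree(1.0 - corr)
        # fcluster merges at cophenetic distance <= t; the contract is
        # a strict < cut_height, so step just below the cut
        groups = fcluster(z, t=np.nextafter(cut_height, 0.0), criterion="distance")
        order = list(eig.index)
        merged_any = False
        mapping: dict[str, str] = {}
        for gid in np.unique(groups):
            members = [order[i] for i in np.flatnonzero(groups == gid)]
            if len(members) > 1:
                target = max(members, key=lambda m: len(modules[m]))
                for m in members:
                    if m != target:
                        mapping[m] = target
                        merged_any = True
        if not merged_any:
            break
        logger.info("merging modules: %s", mapping)
        part = part.relabel(mapping)
    eig, _ = eigengene_matrix(matrix, part)
    return part, eig


def kme(matrix: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Module membership: gene x module Pearson correlation with eigengenes.

    Constant genes get NaN (flagged missing).
    """
    if list(matrix.columns) != list(eigengenes.columns):
        eigengenes = eigengenes[matrix.columns]
    x, keep_g = _standardize_rows(matrix.to_numpy(dtype=float))
    e, _ = _standardize_rows(eigengenes.to_numpy(dtype=float))
    n = matrix.shape[1]
    k = (x @ e.T) / n
    k[~keep_g, :] = np.nan
    return pd.DataFrame(np.clip(k, -1.0, 1.0),
                        index=matrix.index, columns=eigengenes.index)


# ---------------------------------------------------------------------------
# correlation reports
# ---------------------------------------------------------------------------

def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided Student-t p-value of a Pearson correlation, df = n - 2."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def module_correlations(
    eigengenes: pd.DataFrame,
    design: SampleDesign | None = None,
    traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Module-sample and module-trait Pearson correlation report.

    Module-sample correlation follows the classical recipe: the
    eigengene against the one-hot indicator of each stage's samples.
    Traits (samples x traits) are correlated directly. p-values are
    two-sided Student-t with df = n - 2.
    """
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    rows = []
    targets: list[tuple[str, str, np.ndarray]] = []
    if design is not None:
        design.check_covers(eigengenes.columns)
        for stage in design.stages:
            ind = design.stage_indicator(stage).reindex(eigengenes.columns)
            targets.append(("stage", stage, ind.to_numpy(dtype=float)))
    if traits is not None:
        t = traits.reindex(eigengenes.columns)
        if t.isna().any().any():
            raise ValueError("trait table does not cover all samples")
        for name in t.columns:
            targets.append(("trait", name, t[name].to_numpy(dtype=float)))
    for module in eigengenes.index:
        e = eigengenes.loc[module].to_numpy(dtype=float)
        for kind, name, vec in targets:
            r = _pearson(e, vec)
            p = np.nan if np.isnan(r) else correlation_pvalue(r, n)
            rows.append({"module": module, "kind": kind, "target": name,
                         "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Weighted coexpression network model over an FPKM matrix.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples FPKM-scale abundances (typically the DEG union
        after the expressed filter).
    design : SampleDesign
    power : float
        Soft-threshold exponent beta (default 12).
    signed : bool
        Use the signed adjacency variant (default False, unsigned).
    min_module_size : int
    merge_cut_height : float
        Eigengene-dissimilarity cut below which modules merge.
    input_transform : {"log2", "log10", "none"}
        Transform applied before correlation; log2(FPKM + 1) by default,
        since correlation on the raw FPKM scale is dominated by the
        right tail.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        design: SampleDesign | None = None,
        power: float = 12,
        signed: bool = False,
        min_module_size: int = 50,
        merge_cut_height: float = 0.75,
        input_transform: str = "log2",
    ):
        validate_expression(matrix)
        if design is not None:
            design.check_covers(matrix.columns)
        self.matrix = matrix
        self.design = design
        self.power = power
        self.signed = signed
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        if input_transform not in {"log2", "log10", "none"}:
            raise ValueError(f"unknown input_transform {input_transform!r}")
        self.input_transform = input_transform

    def _transformed(self) -> pd.DataFrame:
        x = self.matrix.to_numpy(dtype=float)
        if self.input_transform == "log2":
            x = np.log2(x + 1.0)
        elif self.input_transform == "log10":
            x = np.log10(x + 0.01)
        return pd.DataFrame(x, index=self.matrix.index, columns=self.matrix.columns)

    def fit(self) -> "CoexpressionResults":
        x = self._transformed()
        sd = x.std(axis=1)
        excluded = list(x.index[sd == 0])
        if excluded:
            logger.warning("excluding %d zero-variance genes from the network",
                           len(excluded))
            x = x.loc[sd > 0]
        adj = soft_adjacency(x, beta=self.power, signed=self.signed)
        tom_m = tom(adj)
        part = detect_modules(tom_m, self.min_module_size)
        if part.modules:
            part, eig = merge_modules(x, part, self.merge_cut_height)
            _, varexp = eigengene_matrix(x, part)
            kme_table = kme(x, eig)
        else:
            eig = pd.DataFrame(columns=x.columns)
            varexp = pd.Series(dtype=float)
            kme_table = pd.DataFrame(index=x.index)
        return CoexpressionResults(
            model=self, transformed=x, tom_=tom_m, partition=part,
            eigengenes=eig, variance_explained=varexp, kme_=kme_table,
            excluded_genes=excluded,
        )


@dataclass
class CoexpressionResults:
    """Fitted coexpression network: modules, eigengenes, kME, reports."""

    model: CoexpressionNetwork
    transformed: pd.DataFrame
    tom_: pd.DataFrame
    partition: ModulePartition
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    kme_: pd.DataFrame
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def design(self) -> SampleDesign | None:
        return self.model.design

    @property
    def module_sizes(self) -> pd.Series:
        return self.partition.module_sizes

    def preponderant_stages(self) -> dict[str, str]:
        """Stage at which each module's eigengene peaks (mean over replicates)."""
        if self.design is None:
            raise ValueError("no design attached")
        out = {}
        for module in self.eigengenes.index:
            e = self.eigengenes.loc[module]
            means = {
                stage: float(e[self.design.samples_in_stage(stage)].mean())
                for stage in self.design.stages
            }
            out[module] = max(means, key=means.get)
        return out

    def module_sample_correlations(self) -> pd.DataFrame:
        return module_correlations(self.eigengenes, design=self.design)

    def module_trait_correlations(self, traits: pd.DataFrame) -> pd.DataFrame:
        return module_correlations(self.eigengenes, traits=traits)

    def summary(self) -> pd.DataFrame:
        """One row per module: size, variance explained, peak stage."""
        sizes = self.module_sizes
        peak = self.preponderant_stages() if self.design is not None else {}
        rows = [
            {
                "module": m,
                "n_genes": int(sizes.get(m, 0)),
                "variance_explained": float(self.variance_explained.get(m, np.nan)),
                "preponderant_stage": peak.get(m, ""),
            }
            for m in self.eigengenes.index
        ]
        rows.append({
            "module": UNASSIGNED,
            "n_genes": int((self.partition.labels == UNASSIGNED).sum()),
            "variance_explained": np.nan,
            "preponderant_stage": "",
        })
        return pd.DataFrame(rows)
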