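"""Hypergeometric over-representation testing for module gene sets.

Given a module's gene set of size n drawn from a universe of M
annotated genes, a term annotating K universe genes with k hits inside
the set has the upper-tail p-value

    p = sum_{j >= k} C(K, j) C(M - K, n - j) / C(M, n),

identical to the one-sided Fisher exact test on the 2x2 table. p is
exactly 1 when k = 0. Benjamini-Hochberg q-values are reported
alongside raw p, since module-level reporting conventionally uses raw p
at a 0.01 or 0.05 cut.

The default universe is every gene carrying at least one term; pass an
explicit universe (e.g. all expressed genes) to change the background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationTable", "hypergeom_enrich", "bh_adjust"]


@dataclass
class AnnotationTable:
    """gene -> terms mapping with a fixed universe."""

    gene_to_terms: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] | None = None

    def __post_init__(self):
        outside = set(self.gene_to_terms) - self.universe
        if outside:
            raise ValueError(
                f"annotated genes outside the universe: {sorted(outside)[:10]}")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        gene_col: str = "gene",
        term_col: str = "term",
        universe: Iterable[str] | None = None,
    ) -> "AnnotationTable":
        """Build from a long (gene, term) table; duplicates are an error."""
        if frame.duplicated([gene_col, term_col]).any():
            dups = frame[frame.duplicated([gene_col, term_col])]
            raise ValueError(f"duplicate (gene, term) pairs:\n{dups.head()}")
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(frame[gene_col], frame[term_col]):
            mapping.setdefault(str(gene), set()).add(str(term))
        uni = set(map(str, universe)) if universe is not None else set(mapping)
        return cls(mapping, uni)

    def term_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                sizes[t] = sizes.get(t, 0) + 1
        return sizes

    def genes_of(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if term in ts}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    geneset: Iterable[str],
    annotation: AnnotationTable,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every annotated term.

    Returns a DataFrame (term, k, K, n, M, p, q) sorted by p. Terms with
    no universe annotation are skipped; genes outside the universe are
    an error.
    """
    geneset = set(map(str, geneset))
    outside = geneset - annotation.universe
    if outside:
        raise ValueError(f"genes outside the annotation universe: {sorted(outside)[:10]}")
    m_total = len(annotation.universe)
    n = len(geneset)
    rows = []
    for term, k_total in sorted(annotation.term_sizes().items()):
        if k_total == 0:
            continue
        hits = len(geneset & annotation.genes_of(term))
        # survival function at k-1 gives P(X >= k); exact log-space tail
        p = float(stats.hypergeom.sf(hits - 1, m_total, k_total, n))
        rows.append({"term": term, "k": hits, "K": k_total,
                     "n": n, "M": m_total, "p": min(max(p, 0.0), 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "M", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def prune_by_parent(
    results: pd.DataFrame,
    parents: Mapping[str, str],
) -> pd.DataFrame:
    """Optional convenience: drop a term when an ancestor has smaller p.

    ``parents`` maps term -> parent term. This is a light redundancy
    filter, not a semantic-similarity reduction.
    """
    pvals = dict(zip(results["term"], results["p"]))

    def ancestor_beats(term: str) -> bool:
        seen = set()
        cur = parents.get(term)
        while cur is not None and cur not in seen:
            if cur in pvals and pvals[cur] < pvals[term]:
                return True
            seen.add(cur)
            cur = parents.get(cur)
        return False

    keep = [not ancestor_beats(t) for t in results["term"]]
    return results[keep].reset_index(drop=True)
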