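"""Hypergeometric over-representation of gene sets.

Given a query gene list, a collection of flat named gene sets (GO- or
KEGG-style term -> genes tables) and an explicit gene universe, each
retained set is scored with the one-sided hypergeometric tail
P(X >= k) for k = |query ∩ set|, population N = |universe|, K = |set| and
n = |query|; p-values are Benjamini-Hochberg adjusted across the retained
sets. Defaults follow the published filters: terms with at least 30 genes,
adjusted-p cutoff 0.01 for GO-style and 0.05 for KEGG-style collections.
Term-hierarchy propagation is out of scope: collections are flat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger("hippolink")


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a declared universe."""

    sets: dict[str, frozenset]
    universe: frozenset
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.universe) == 0:
            raise ValueError("universe must be non-empty")
        restricted = {}
        dropped = {}
        for name, genes in self.sets.items():
            inside = frozenset(genes) & self.universe
            n_out = len(genes) - len(inside)
            if n_out:
                dropped[name] = n_out
            restricted[name] = inside
        if len(restricted) != len(self.sets):
            raise ValueError("set names must be unique")
        self.sets = restricted
        self.dropped = dropped

    @classmethod
    def from_tsv(cls, path: str | Path, universe) -> "GeneSetCollection":
        """Two-column TSV (term_id, gene_id), one membership per line."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected columns term_id, gene_id")
        term_col, gene_col = df.columns[:2]
        sets = {
            term: frozenset(sub[gene_col])
            for term, sub in df.groupby(term_col, observed=True)
        }
        return cls(sets=sets, universe=frozenset(universe))


def hypergeom_enrich(
    query,
    collection: GeneSetCollection,
    min_set_size: int = 30,
    padj_cutoff: float = 0.01,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test.

    Query genes outside the universe are dropped (count logged). Sets with
    fewer than ``min_set_size`` genes inside the universe are skipped before
    testing and before the BH adjustment. The table is sorted by padj, then
    p, then set name, with an ``enriched`` flag at ``padj < padj_cutoff``.
    """
    query = frozenset(query)
    if not query:
        raise ValueError("query gene set is empty")
    inside = query & collection.universe
    n_dropped = len(query) - len(inside)
    if n_dropped:
        logger.info("dropped %d query genes outside the universe", n_dropped)
    if not inside:
        raise ValueError("no query genes inside the universe")

    N = len(collection.universe)
    n = len(inside)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        if K < min_set_size:
            continue
        k = len(inside & genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, N, K, n, k, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set_name", "universe_size", "set_size", "query_size", "overlap", "pvalue"]
    )
    if len(table):
        table["padj"] = bh_adjust(table["pvalue"].to_numpy())
        table["enriched"] = table["padj"] < padj_cutoff
        table = table.sort_values(
            ["padj", "pvalue", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["padj"] = pd.Series(dtype=float)
        table["enriched"] = pd.Series(dtype=bool)
    return table
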