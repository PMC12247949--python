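"""Promoter-window peak annotation and target-set intersection statistics.

A peak is "in the promoter" of a gene when its interval shares at least one
base with the gene's promoter window. The window is the 1,500 bp flanking
the transcription start site, interpreted symmetrically by default:
[TSS - flank, TSS + flank + 1) in 0-based half-open coordinates (3,001
bases including the TSS base for the default flank). An upstream-only mode
([TSS - flank, TSS + 1) on +, strand-mirrored on -) is available because the
phrase "flanking the TSS" does not disambiguate the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneAnnotation, PeakSet

logger = logging.getLogger("hippolink")


def promoter_windows(
    genes: GeneAnnotation, flank: int = 1500, mode: str = "symmetric"
) -> pd.DataFrame:
    """Per-gene promoter window [start, end) plus the TSS, 0-based half-open."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if mode not in ("symmetric", "upstream"):
        raise ValueError("mode must be 'symmetric' or 'upstream'")
    g = genes.genes
    tss = genes.tss.to_numpy()
    if mode == "symmetric":
        start = tss - flank
        end = tss + flank + 1
    else:
        plus = g["strand"].to_numpy() == "+"
        start = np.where(plus, tss - flank, tss)
        end = np.where(plus, tss + 1, tss + flank + 1)
    return pd.DataFrame(
        {
            "gene_id": g["gene_id"].to_numpy(),
            "chrom": g["chrom"].to_numpy(),
            "start": np.maximum(start, 0),
            "end": end,
            "tss": tss,
        }
    )


@dataclass
class PromoterAssignment:
    table: pd.DataFrame  # per peak: in_promoter, gene_id, tss_distance
    promoter_fraction: float | None  # None for an empty peak set
    target_genes: frozenset

    def summary(self) -> dict:
        return {
            "n_peaks": len(self.table),
            "n_in_promoter": int(self.table["in_promoter"].sum()) if len(self.table) else 0,
            "promoter_fraction": self.promoter_fraction,
            "n_target_genes": len(self.target_genes),
        }


def assign_promoter(
    peaks: PeakSet,
    genes: GeneAnnotation,
    flank: int = 1500,
    mode: str = "symmetric",
    fallback_nearest: bool = False,
) -> PromoterAssignment:
    """Assign peaks to genes via promoter-window overlap.

    A peak overlapping several windows is assigned to the overlapped gene
    whose TSS is nearest the peak midpoint (ties to the lexicographically
    smallest gene ID). With ``fallback_nearest`` peaks outside every window
    are additionally annotated with their nearest gene (but still counted as
    outside promoters). Unknown peak chromosomes raise.
    """
    win = promoter_windows(genes, flank=flank, mode=mode)
    gene_chroms = set(win["chrom"])
    peak_chroms = set(peaks.peaks["chrom"]) if len(peaks) else set()
    unknown = sorted(peak_chroms - gene_chroms)
    if unknown:
        raise ValueError(f"peaks on chromosomes absent from the annotation: {unknown}")

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in win.groupby("chrom", observed=True):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), (gid, int(t)))
            for s, e, gid, t in zip(sub["start"], sub["end"], sub["gene_id"], sub["tss"])
        )

    rows = []
    for row in peaks.peaks.sort_values("peak_id", kind="mergesort").itertuples(index=False):
        mid = (row.start + row.end - 1) // 2
        hits = trees[row.chrom][row.start:row.end]
        if hits:
            best = min(hits, key=lambda iv: (abs(mid - iv.data[1]), iv.data[0]))
            rows.append((row.peak_id, True, best.data[0], int(mid - best.data[1])))
        elif fallback_nearest:
            gid, dist = _nearest_on_chrom(genes, row.chrom, mid)
            rows.append((row.peak_id, False, gid, dist))
        else:
            rows.append((row.peak_id, False, None, None))
    table = pd.DataFrame(rows, columns=["peak_id", "in_promoter", "gene_id", "tss_distance"])
    frac = float(table["in_promoter"].mean()) if len(table) else None
    targets = frozenset(table.loc[table["in_promoter"], "gene_id"])
    if fallback_nearest:
        targets = frozenset(table["gene_id"].dropna())
    return PromoterAssignment(table=table, promoter_fraction=frac, target_genes=targets)


def _nearest_on_chrom(genes: GeneAnnotation, chrom: str, pos: int):
    g = genes.genes
    tss = genes.tss
    mask = (g["chrom"] == chrom).to_numpy()
    if not mask.any():
        return None, None
    ids = g.loc[mask, "gene_id"].to_numpy()
    t = tss.to_numpy()[mask]
    d = np.abs(pos - t)
    best = np.flatnonzero(d == d.min())
    pick = best[np.argsort(ids[best], kind="mergesort")[0]]
    return ids[pick], int(pos - t[pick])


def nearest_gene(peaks: PeakSet, genes: GeneAnnotation) -> pd.DataFrame:
    """Map each peak to the gene with the nearest TSS on its chromosome.

    Distance is |peak midpoint - TSS|; ties break to the lexicographically
    smallest gene ID. Peaks on gene-free chromosomes get no assignment
    (their count is logged).
    """
    rows = []
    n_unassigned = 0
    for row in peaks.peaks.itertuples(index=False):
        mid = (row.start + row.end - 1) // 2
        gid, dist = _nearest_on_chrom(genes, row.chrom, mid)
        if gid is None:
            n_unassigned += 1
        rows.append((row.peak_id, gid, dist))
    if n_unassigned:
        logger.info("%d peaks on gene-free chromosomes left unassigned", n_unassigned)
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "signed_distance"])


@dataclass
class IntersectionSummary:
    """Membership-multiplicity statistics over several target gene sets."""

    set_sizes: list[int]
    unique_to_one: frozenset
    common_to_all: frozenset
    common_to_2plus: frozenset

    def counts(self) -> dict[str, int]:
        return {
            "n_sets": len(self.set_sizes),
            "set_sizes": self.set_sizes,
            "union": len(self.unique_to_one) + len(self.common_to_2plus),
            "unique_to_one": len(self.unique_to_one),
            "common_to_all": len(self.common_to_all),
            "common_to_2plus": len(self.common_to_2plus),
        }


def target_sets_intersection(sets) -> IntersectionSummary:
    """Count genes by how many of the input sets contain them.

    ``unique_to_one`` holds genes in exactly one set, ``common_to_all``
    those in every set, ``common_to_2plus`` those in at least two; with a
    single input set all genes are both unique and common-to-all.
    """
    sets = [frozenset(s) for s in sets]
    if len(sets) == 0:
        raise ValueError("need at least one gene set")
    mult: dict[str, int] = {}
    for s in sets:
        for g in s:
            mult[g] = mult.get(g, 0) + 1
    n = len(sets)
    return IntersectionSummary(
        set_sizes=[len(s) for s in sets],
        unique_to_one=frozenset(g for g, m in mult.items() if m == 1),
        common_to_all=frozenset(g for g, m in mult.items() if m == n),
        common_to_2plus=frozenset(g for g, m in mult.items() if m >= 2),
    )
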