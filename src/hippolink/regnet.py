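"""Heterogeneous regulatory network and shortest-path connector search.

The network joins a directed TF->gene layer with an undirected
protein-protein interaction (PPI) layer: TF-gene edges are traversable only
from the regulator to the target, PPI edges in both directions. Each edge
carries its type and a provenance label (e.g. curated-database-like vs
ChIP-derived). The scientific question the module answers: along which
shortest regulatory route could gene A influence gene B, and which nodes
(connectors) do all such routes pass through? In the study system the unique
two-step answer between *hpo* and *yki* is *chinmo*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

UNREACHABLE = math.inf


@dataclass
class RegulatoryNetwork:
    """Typed edge set: directed ``tfgene`` edges + canonical ``ppi`` pairs."""

    tfgene: set = field(default_factory=set)  # (source, target)
    ppi: set = field(default_factory=set)  # sorted (a, b) pairs
    provenance: dict = field(default_factory=dict)  # (type, u, v) -> label
    self_loops: set = field(default_factory=set)

    @property
    def nodes(self) -> frozenset:
        out = set()
        for u, v in self.tfgene:
            out.add(u)
            out.add(v)
        for a, b in self.ppi:
            out.add(a)
            out.add(b)
        return frozenset(out)

    @property
    def n_edges(self) -> int:
        return len(self.tfgene) + len(self.ppi)

    def directed_expansion(self) -> nx.DiGraph:
        """Traversal graph: each PPI pair becomes two arcs; self-loops dropped."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.tfgene:
            if u != v:
                g.add_edge(u, v)
        for a, b in self.ppi:
            if a != b:
                g.add_edge(a, b)
                g.add_edge(b, a)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, "tfgene", self.provenance.get(("tfgene", u, v), "user"))
            for u, v in sorted(self.tfgene)
        ] + [
            (a, b, "ppi", self.provenance.get(("ppi", a, b), "user"))
            for a, b in sorted(self.ppi)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "type", "provenance"])


def build_network(
    tfgene_edges: pd.DataFrame | None = None,
    ppi_edges: pd.DataFrame | None = None,
    chip_edges: list[tuple[pd.DataFrame, str]] | None = None,
) -> tuple[RegulatoryNetwork, dict]:
    """Join TF->gene, PPI and ChIP-derived edge lists into one network.

    ChIP edge frames enter as directed ``tfgene`` edges under the given
    provenance label (e.g. ``chip-yki``). Duplicate (source, target, type)
    triples are dropped (first provenance wins); PPI pairs are stored
    canonically once. Self-loops are kept in the edge set but flagged and
    ignored during path search. Returns the network and a summary dict.
    """
    net = RegulatoryNetwork()
    dup = 0

    def add_tfgene(u: str, v: str, prov: str):
        nonlocal dup
        if (u, v) in net.tfgene:
            dup += 1
            return
        net.tfgene.add((u, v))
        net.provenance[("tfgene", u, v)] = prov
        if u == v:
            net.self_loops.add((u, v))

    def add_ppi(a: str, b: str, prov: str):
        nonlocal dup
        pair = tuple(sorted((a, b)))
        if pair in net.ppi:
            dup += 1
            return
        net.ppi.add(pair)
        net.provenance[("ppi", *pair)] = prov
        if a == b:
            net.self_loops.add(pair)

    frames: list[tuple[pd.DataFrame, str | None]] = []
    if tfgene_edges is not None:
        frames.append((tfgene_edges, None))
    if ppi_edges is not None:
        frames.append((ppi_edges, None))
    for chip_df, label in chip_edges or []:
        df = chip_df.copy()
        df["type"] = "tfgene"
        df["provenance"] = label
        frames.append((df, label))

    for df, _ in frames:
        for row in df.itertuples(index=False):
            prov = getattr(row, "provenance", "user")
            etype = getattr(row, "type", "tfgene")
            if etype == "tfgene":
                add_tfgene(row.source, row.target, prov)
            elif etype == "ppi":
                add_ppi(row.source, row.target, prov)
            else:
                raise ValueError(f"unknown edge type {etype!r}")

    summary = {
        "n_nodes": len(net.nodes),
        "n_tfgene": len(net.tfgene),
        "n_ppi": len(net.ppi),
        "n_self_loops": len(net.self_loops),
        "duplicates_dropped": dup,
    }
    return net, summary


def shortest_regulatory_path(
    net: RegulatoryNetwork, src: str, dst: str, max_paths: int = 1000
) -> tuple[float, list[list[str]], bool]:
    """All shortest directed routes from ``src`` to ``dst``.

    Returns ``(length, paths, truncated)``: the minimal edge count, every
    distinct shortest node sequence in lexicographic order (capped at
    ``max_paths``; ``truncated`` flags the cap), or ``(inf, [], False)``
    when ``dst`` is unreachable. ``src == dst`` gives length 0 and the
    single trivial path.
    """
    nodes = net.nodes
    for x in (src, dst):
        if x not in nodes:
            raise KeyError(f"node {x!r} not in network")
    if src == dst:
        return 0.0, [[src]], False
    g = net.directed_expansion()
    try:
        paths = []
        truncated = False
        for i, p in enumerate(nx.all_shortest_paths(g, src, dst)):
            if i >= max_paths:
                truncated = True
                break
            paths.append(list(p))
    except nx.NetworkXNoPath:
        return UNREACHABLE, [], False
    paths.sort()
    return float(len(paths[0]) - 1), paths, truncated


def enumerate_connectors(
    net: RegulatoryNetwork, src: str, dst: str, max_paths: int = 1000
) -> dict:
    """Interior nodes of the shortest src->dst routes.

    ``unique`` is True exactly when the shortest length is 2 and a single
    connector carries every shortest route. A direct src->dst edge yields
    length 1 with an empty connector set.
    """
    length, paths, truncated = shortest_regulatory_path(net, src, dst, max_paths=max_paths)
    connectors: set[str] = set()
    for p in paths:
        connectors.update(p[1:-1])
    return {
        "length": length,
        "connectors": frozenset(connectors),
        "unique": length == 2 and len(connectors) == 1,
        "n_paths": len(paths),
        "truncated": truncated,
    }


def target_overlap_stats(de_result, targets) -> dict:
    """Overlap between a DE result and a putative direct-target gene set.

    Returns the fraction of significantly downregulated genes that are
    targets (``frac_down_in_targets``), and, among targets that are
    differentially expressed at all, the fraction that are downregulated
    (``frac_targets_down``). An empty denominator yields 0.0.
    """
    t = de_result.table
    sig = t[t["significant"]]
    down = set(sig.index[sig["log2FC"] < 0])
    targets = set(targets)
    de_targets = set(sig.index) & targets
    frac_a = len(down & targets) / len(down) if down else 0.0
    frac_b = len(down & de_targets) / len(de_targets) if de_targets else 0.0
    return {
        "n_sig": len(sig),
        "n_down": len(down),
        "n_targets": len(targets),
        "n_de_targets": len(de_targets),
        "frac_down_in_targets": frac_a,
        "frac_targets_down": frac_b,
    }
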