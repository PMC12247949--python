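"""Network construction and connector search against an exhaustive oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hippolink import regnet, synth


def brute_force_shortest(arcs, src, dst):
    """All shortest simple paths by exhaustive DFS over directed arcs."""
    adj = {}
    for u, v in arcs:
        adj.setdefault(u, set()).add(v)
    best = math.inf
    paths = []

    def dfs(node, path):
        nonlocal best, paths
        if len(path) - 1 > best:
            return
        if node == dst:
            L = len(path) - 1
            if L < best:
                best, paths = L, [list(path)]
            elif L == best:
                paths.append(list(path))
            return
        for nxt in sorted(adj.get(node, ())):
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    if src == dst:
        return 0, [[src]]
    dfs(src, [src])
    return (best, sorted(paths)) if paths else (math.inf, [])


def _net_from_arcs(tf_arcs, ppi_pairs):
    tf = pd.DataFrame(tf_arcs, columns=["source", "target"])
    tf["type"] = "tfgene"
    tf["provenance"] = "user"
    ppi = pd.DataFrame(ppi_pairs, columns=["source", "target"])
    ppi["type"] = "ppi"
    ppi["provenance"] = "user"
    net, _ = regnet.build_network(tf if len(tf) else None, ppi if len(ppi) else None)
    return net


MOTIF = _net_from_arcs(
    [("chinmo", "yki"), ("chinmo", "hpo"), ("yki", "chinmo")], [("hpo", "chinmo")]
)


class TestBuildNetwork:
    def test_duplicate_tfgene_and_distinct_ppi_coexist(self):
        tf = pd.DataFrame(
            {"source": ["X", "X"], "target": ["Y", "Y"], "type": "tfgene", "provenance": "user"}
        )
        ppi = pd.DataFrame(
            {"source": ["X"], "target": ["Y"], "type": "ppi", "provenance": "user"}
        )
        net, summary = regnet.build_network(tf, ppi)
        assert net.n_edges == 2
        assert summary["duplicates_dropped"] == 1

    def test_empty_inputs_give_empty_network(self):
        net, summary = regnet.build_network()
        assert summary["n_nodes"] == 0 and net.n_edges == 0

    def test_counts_match_exhaustive_set_construction(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(15)]
        tf_rows = [(nodes[rng.integers(15)], nodes[rng.integers(15)]) for _ in range(60)]
        ppi_rows = [(nodes[rng.integers(15)], nodes[rng.integers(15)]) for _ in range(60)]
        net = _net_from_arcs(tf_rows, ppi_rows)
        expected_tf = {(u, v) for u, v in tf_rows}
        expected_ppi = {tuple(sorted(p)) for p in ppi_rows}
        assert net.tfgene == expected_tf
        assert net.ppi == expected_ppi

    def test_ppi_stored_canonically_once(self):
        net = _net_from_arcs([], [("b", "a"), ("a", "b")])
        assert net.ppi == {("a", "b")}

    def test_chip_edges_carry_provenance(self):
        chip = pd.DataFrame({"source": ["yki"], "target": ["g1"]})
        net, _ = regnet.build_network(chip_edges=[(chip, "chip-yki")])
        assert net.provenance[("tfgene", "yki", "g1")] == "chip-yki"


class TestShortestPath:
    def test_planted_motif_two_steps_via_chinmo(self):
        length, paths, truncated = regnet.shortest_regulatory_path(MOTIF, "hpo", "yki")
        assert length == 2
        assert paths == [["hpo", "chinmo", "yki"]]
        assert not truncated

    def test_src_equals_dst(self):
        length, paths, _ = regnet.shortest_regulatory_path(MOTIF, "hpo", "hpo")
        assert length == 0 and paths == [["hpo"]]

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            regnet.shortest_regulatory_path(MOTIF, "hpo", "nope")

    def test_tfgene_directionality_respected(self):
        net = _net_from_arcs([("Y", "X")], [])
        length, paths, _ = regnet.shortest_regulatory_path(net, "X", "Y")
        assert length == math.inf and paths == []

    def test_ppi_traversable_both_ways(self):
        net = _net_from_arcs([], [("A", "B")])
        for src, dst in (("A", "B"), ("B", "A")):
            length, paths, _ = regnet.shortest_regulatory_path(net, src, dst)
            assert length == 1

    def test_path_lengths_equal_edge_counts(self):
        length, paths, _ = regnet.shortest_regulatory_path(MOTIF, "yki", "hpo")
        for p in paths:
            assert len(p) - 1 == length

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        """200 seeded random graphs of <= 12 nodes vs brute-force DFS."""
        rng = np.random.default_rng(77)
        for trial in range(200):
            n = int(rng.integers(3, 13))
            nodes = [f"n{i}" for i in range(n)]
            n_tf = int(rng.integers(0, 2 * n))
            n_ppi = int(rng.integers(0, n))
            tf_rows = [
                (nodes[rng.integers(n)], nodes[rng.integers(n)]) for _ in range(n_tf)
            ]
            ppi_rows = [
                (nodes[rng.integers(n)], nodes[rng.integers(n)]) for _ in range(n_ppi)
            ]
            tf_rows = [(u, v) for u, v in tf_rows if u != v]
            ppi_rows = [(u, v) for u, v in ppi_rows if u != v]
            net = _net_from_arcs(tf_rows, ppi_rows)
            if len(net.nodes) < 2:
                continue
            pool = sorted(net.nodes)
            src, dst = pool[0], pool[-1]
            arcs = set(tf_rows)
            for a, b in ppi_rows:
                arcs |= {(a, b), (b, a)}
            exp_len, exp_paths = brute_force_shortest(arcs, src, dst)
            length, paths, _ = regnet.shortest_regulatory_path(net, src, dst)
            assert length == exp_len, f"trial {trial}"
            assert paths == exp_paths, f"trial {trial}"
            # connectors agree with brute-force interior extraction
            res = regnet.enumerate_connectors(net, src, dst)
            expected_connectors = set()
            for p in exp_paths:
                expected_connectors.update(p[1:-1])
            assert res["connectors"] == expected_connectors, f"trial {trial}"


class TestConnectors:
    def test_motif_connector_unique(self):
        res = regnet.enumerate_connectors(MOTIF, "hpo", "yki")
        assert res["connectors"] == {"chinmo"}
        assert res["unique"] is True

    def test_parallel_connector_breaks_uniqueness(self):
        net = _net_from_arcs(
            [("chinmo", "yki"), ("other", "yki")],
            [("hpo", "chinmo"), ("hpo", "other")],
        )
        res = regnet.enumerate_connectors(net, "hpo", "yki")
        assert res["connectors"] == {"chinmo", "other"}
        assert res["unique"] is False

    def test_direct_edge_reported_as_length_one_empty_connectors(self):
        net = _net_from_arcs([("hpo", "yki"), ("chinmo", "yki")], [("hpo", "chinmo")])
        res = regnet.enumerate_connectors(net, "hpo", "yki")
        assert res["length"] == 1
        assert res["connectors"] == frozenset()
        assert res["unique"] is False

    def test_removing_connector_disconnects_motif(self):
        # drop every edge touching chinmo from the pure motif
        net = _net_from_arcs([], [])
        net.tfgene = {e for e in MOTIF.tfgene if "chinmo" not in e}
        net.ppi = {e for e in MOTIF.ppi if "chinmo" not in e}
        # keep endpoints in the node namespace
        net.tfgene.add(("yki", "yki_dummy"))
        net.ppi.add(("hpo", "hpo_dummy"))
        length, paths, _ = regnet.shortest_regulatory_path(net, "hpo", "yki")
        assert length == math.inf and paths == []

    def test_self_loops_ignored_in_search(self):
        net = _net_from_arcs([("A", "A"), ("A", "B")], [])
        length, paths, _ = regnet.shortest_regulatory_path(net, "A", "B")
        assert length == 1 and paths == [["A", "B"]]

    def test_path_cap_flags_truncation(self):
        # K(1, m, 1)-style layered graph with many parallel 2-paths
        mids = [f"m{i}" for i in range(30)]
        net = _net_from_arcs(
            [("s", m) for m in mids] + [(m, "t") for m in mids], []
        )
        length, paths, truncated = regnet.shortest_regulatory_path(net, "s", "t", max_paths=10)
        assert length == 2 and len(paths) == 10 and truncated


class TestTargetOverlap:
    def _de(self, rows):
        tab = pd.DataFrame(
            {
                "baseMean": 10.0,
                "log2FC": [r[0] for r in rows.values()],
                "SE": 0.1,
                "stat": 0.0,
                "pvalue": [r[1] for r in rows.values()],
                "padj": [r[1] for r in rows.values()],
            },
            index=pd.Index(list(rows), name="gene_id"),
        )
        tab["significant"] = tab["padj"] < 0.05
        from hippolink.de import DEResult

        return DEResult(tab)

    def test_all_down_genes_as_targets_gives_one(self):
        de_res = self._de({"a": (-1, 0.01), "b": (-2, 0.01), "c": (1, 0.01), "d": (1, 0.5)})
        stats = regnet.target_overlap_stats(de_res, {"a", "b"})
        assert stats["frac_down_in_targets"] == 1.0
        assert stats["frac_targets_down"] == 1.0

    def test_disjoint_targets_give_zero(self):
        de_res = self._de({"a": (-1, 0.01), "b": (1, 0.01)})
        stats = regnet.target_overlap_stats(de_res, {"zz"})
        assert stats["frac_down_in_targets"] == 0.0
        assert stats["frac_targets_down"] == 0.0

    def test_matches_exhaustive_set_counting(self):
        rng = np.random.default_rng(10)
        rows = {
            f"g{i}": (float(rng.normal()), float(rng.uniform()))
            for i in range(200)
        }
        de_res = self._de(rows)
        targets = set(rng.choice(list(rows), size=60, replace=False))
        stats = regnet.target_overlap_stats(de_res, targets)
        down = {g for g, (l, p) in rows.items() if p < 0.05 and l < 0}
        sig = {g for g, (l, p) in rows.items() if p < 0.05}
        exp_a = len(down & targets) / len(down)
        exp_b = len(down & (sig & targets)) / len(sig & targets)
        assert stats["frac_down_in_targets"] == exp_a
        assert stats["frac_targets_down"] == exp_b
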