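#!/usr/bin/env python
"""Regulatory-network construction and the hpo -> yki connector search.

The TF-gene and PPI edge lists are merged with ChIP-derived yki->target
edges (the common-to-all target set from step 06) into one typed network:
TF-gene edges directed, PPI edges bidirectional. A breadth-first search then
asks along which shortest route hpo could regulate yki transcription. With
the planted motif the answer is the two-step route through chinmo, and
chinmo is the unique connector. Finally, the DE results are intersected
with the ChIP target set to measure how much of the germ-line downregulated
response is attributable to putative direct yki targets.
"""

import json
import math
from pathlib import Path

import pandas as pd

from hippolink.de import DEResult
from hippolink.io import read_edges, write_edges
from hippolink.regnet import build_network, enumerate_connectors, target_overlap_stats

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tf = read_edges(BASE / "simulated" / "edges_tfgene.tsv")
    ppi = read_edges(BASE / "simulated" / "edges_ppi.tsv")
    common = [
        g for g in (BASE / "targets_common_to_all.txt").read_text().splitlines() if g
    ]
    chip = pd.DataFrame({"source": "yki", "target": common})
    net, summary = build_network(tf, ppi, chip_edges=[(chip, "chip-yki")])
    write_edges(net.to_edge_frame(), BASE / "network_edges.tsv")
    print(
        f"network: {summary['n_nodes']} nodes, {summary['n_tfgene']} tfgene + "
        f"{summary['n_ppi']} ppi edges ({summary['duplicates_dropped']} duplicates dropped)"
    )

    res = enumerate_connectors(net, "hpo", "yki")
    report = {
        "network": summary,
        "length": res["length"] if math.isfinite(res["length"]) else "inf",
        "connectors": sorted(res["connectors"]),
        "unique": res["unique"],
        "n_paths": res["n_paths"],
    }
    print(
        f"shortest hpo->yki route: {res['length']:.0f} steps via "
        f"{sorted(res['connectors'])} (unique connector: {res['unique']})"
    )

    report["target_overlap"] = {}
    for name in ("germ_hpo", "germ_yki"):
        de_res = DEResult(pd.read_csv(BASE / f"de_{name}.tsv", sep="\t", index_col=0))
        stats = target_overlap_stats(de_res, common)
        report["target_overlap"][name] = stats
        print(
            f"{name}: {100 * stats['frac_down_in_targets']:.1f}% of downregulated genes "
            f"are chip targets; {100 * stats['frac_targets_down']:.1f}% of DE targets are down"
        )

    with open(BASE / "connector_report.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
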