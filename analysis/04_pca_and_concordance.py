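#!/usr/bin/env python
"""Sample PCA and knockdown-concordance statistics.

First, PCA on VST-transformed counts asks which experimental factor drives
expression variation: with the planted design, cell type should dominate
PC1. Second, the germ-line and soma DE results from step 03 are partitioned
into shared / opposite / exclusive gene sets — the expectation is high
hpo/yki concordance in the germ line and near-complete genotype-exclusivity
in the soma, with the planted opposite classes (1 germ gene, 4 soma genes)
surfacing in the "opposite" partition.
"""

import json
from pathlib import Path

import pandas as pd

from hippolink import transcriptomics as tx
from hippolink.de import DEResult, vst_transform
from hippolink.io import read_counts, read_metadata

BASE = Path(__file__).resolve().parent.parent / "results"


def load_de(name: str) -> DEResult:
    return DEResult(pd.read_csv(BASE / f"de_{name}.tsv", sep="\t", index_col=0))


def main() -> None:
    counts = read_counts(BASE / "simulated" / "counts.tsv")
    meta = read_metadata(BASE / "simulated" / "metadata.tsv")

    res = tx.pca(vst_transform(counts))
    res.scores.rename_axis("sample_id").to_csv(BASE / "pca_scores.tsv", sep="\t")
    res.variance_fraction.rename_axis("component").to_csv(BASE / "pca_variance.tsv", sep="\t")
    pc1 = 100 * res.variance_fraction.iloc[0]
    r2 = {
        f: tx.factor_variance_attribution(res.scores, meta, f).iloc[0]
        for f in ("cell_type", "stage", "genotype")
    }
    print(f"PC1 explains {pc1:.1f}% of variance; factor R^2 on PC1: "
          + ", ".join(f"{k}={v:.2f}" for k, v in r2.items()))

    report = {"pc1_variance_pct": pc1, "pc1_r2": r2, "overlap": {}}
    for label, (a, b) in {"germ": ("germ_hpo", "germ_yki"),
                          "soma": ("soma_hpo", "soma_yki")}.items():
        part = tx.classify_de_overlap(load_de(a), load_de(b))
        raw, pct = tx.shared_fraction(part)
        counts_d = part.counts()
        report["overlap"][label] = {**counts_d, "shared_fraction_pct": pct}
        rows = [
            (g, cat)
            for cat in ("shared_up", "shared_down", "opposite", "exclusive_a", "exclusive_b")
            for g in sorted(getattr(part, cat))
        ]
        pd.DataFrame(rows, columns=["gene_id", "category"]).to_csv(
            BASE / f"overlap_{label}.tsv", sep="\t", index=False
        )
        print(
            f"{label}: {pct}% of DE genes shared between hpo and yki knockdowns "
            f"({counts_d['shared_down']} down, {counts_d['shared_up']} up, "
            f"{counts_d['opposite']} opposite)"
        )

    with open(BASE / "pca_concordance_summary.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
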