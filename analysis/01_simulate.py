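#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes the 48-library count matrix (germ/soma x early/mid/late x
control/hpo_RNAi/yki_RNAi), its metadata and planted truth table, a matched
gene annotation, three ChIP-like peak sets with promoter fractions inside
the observed 69-75% range, and the TF-gene + PPI edge lists carrying the
hpo-chinmo-yki motif. Everything downstream (02-07) reads from
results/simulated/.
"""

from pathlib import Path

from hippolink.config import PipelineConfig
from hippolink.io import write_bed, write_counts, write_edges, write_gtf, write_metadata
from hippolink.pipeline import simulate_inputs

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(seed=SEED)
    inputs = simulate_inputs(config, SEED)

    write_counts(inputs["counts"], OUT / "counts.tsv")
    write_metadata(inputs["metadata"], OUT / "metadata.tsv")
    inputs["truth"].rename_axis("gene_id").to_csv(OUT / "truth.tsv", sep="\t")
    write_gtf(inputs["annotation"], OUT / "annotation.gtf")
    for name, ps in inputs["peak_sets"].items():
        write_bed(ps, OUT / f"peaks_{name}.bed")
    write_edges(inputs["tf_edges"], OUT / "edges_tfgene.tsv")
    write_edges(inputs["ppi_edges"], OUT / "edges_ppi.tsv")

    meta = inputs["metadata"]
    print(f"wrote {len(inputs['counts'].gene_ids)} genes x {len(meta)} libraries")
    print(
        f"  soma libraries: {(meta.cell_type == 'soma').sum()}, "
        f"germ controls: {((meta.cell_type == 'germ') & (meta.genotype == 'control')).sum()}, "
        f"germ knockdowns: {((meta.cell_type == 'germ') & (meta.genotype != 'control')).sum()}"
    )
    print(f"  planted outlier control: {inputs['truth'].attrs['outlier_sample']}")
    print(f"  outputs in {OUT}")


if __name__ == "__main__":
    main()
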