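"""End-to-end orchestration: simulate or ingest, then run every stage.

Stage order mirrors the analysis narrative: outlier-control screening,
per-contrast NB differential expression, PCA with factor attribution,
concordance classification of the germ-line and soma knockdown responses,
gene-set over-representation, promoter peak annotation with multi-dataset
intersection, and the regulatory-network connector search. One global seed
is fanned out to fixed per-stage child seeds so each stage is independently
reproducible; two runs with the same seed produce byte-identical bundles.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, enrichment, peaks as pk, regnet, synth, transcriptomics as tx
from .config import PipelineConfig
from .io import (
    CountMatrix,
    write_bed,
    write_counts,
    write_edges,
    write_gtf,
    write_metadata,
)

# fixed offsets fanning the global seed out to stages
_SEED_COUNTS = 11
_SEED_ANNOT = 23
_SEED_PEAKS = 37
_SEED_NET = 53
_SEED_SETS = 71

CONTRAST_SPECS = {
    # name -> (cell_type subset, genotype level A, stages used)
    "germ_hpo": ("germ", "hpo_RNAi", ("mid", "late")),
    "germ_yki": ("germ", "yki_RNAi", ("mid", "late")),
    "soma_hpo": ("soma", "hpo_RNAi", ("early", "mid", "late")),
    "soma_yki": ("soma", "yki_RNAi", ("early", "mid", "late")),
}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, (pd.Series,)):
        return _jsonify(obj.to_dict())
    return obj


def run_contrast(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    name: str,
    alpha: float,
    exclude_samples: list[str] | None = None,
) -> de.DEResult:
    """One named knockdown-vs-control contrast within one cell type."""
    cell_type, level_a, stages = CONTRAST_SPECS[name]
    meta = metadata.loc[counts.sample_ids]
    keep = (meta["cell_type"] == cell_type) & meta["stage"].isin(stages)
    sub_meta = meta[keep]
    sub = counts.subset_samples(list(sub_meta.index))
    covariates = ["stage"] if sub_meta["stage"].nunique() > 1 else []
    return de.wald_de(
        sub,
        sub_meta,
        contrast=("genotype", level_a, "control"),
        alpha=alpha,
        covariates=covariates,
        exclude_samples=exclude_samples,
    )


def simulate_inputs(config: PipelineConfig, seed: int) -> dict:
    """Generate the full synthetic input bundle for one pipeline run."""
    design = synth.DesignSpec()
    counts, metadata, truth = synth.make_counts(design, seed=seed + _SEED_COUNTS)
    annotation = synth.make_annotation(
        n_genes=len(counts.gene_ids),
        n_chroms=3,
        chrom_length=6_000_000,
        seed=seed + _SEED_ANNOT,
        gene_ids=counts.gene_ids,
    )
    # three ChIP-like datasets inside the observed 69-75% promoter range
    peak_sets = {
        name: synth.make_peaks(
            annotation,
            n_peaks=1500,
            promoter_fraction=frac,
            flank=config.promoter_flank,
            seed=seed + _SEED_PEAKS + i,
            name_prefix=f"{name}_",
        )
        for i, (name, frac) in enumerate(
            [("embryo", 0.72), ("disc", 0.70), ("s2", 0.74)]
        )
    }
    tf_edges, ppi_edges = synth.make_network(
        n_tfs=20, n_genes=150, n_tfgene_edges=300, n_ppi_edges=200,
        plant_motif=True, seed=seed + _SEED_NET,
    )
    return {
        "design": design,
        "counts": counts,
        "metadata": metadata,
        "truth": truth,
        "annotation": annotation,
        "peak_sets": peak_sets,
        "tf_edges": tf_edges,
        "ppi_edges": ppi_edges,
    }


def _synthetic_collection(
    universe, truth: pd.DataFrame, seed: int, n_random: int = 12
) -> enrichment.GeneSetCollection:
    """Gene-set collection with one set enriched for the germ-shared class."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    shared = [g for g in truth.index[truth["class"] == "germ_shared"]]
    sets = {}
    planted = set(rng.choice(shared, size=min(60, len(shared)), replace=False))
    padding = rng.choice(universe, size=20, replace=False)
    sets["germ_response_like"] = frozenset(planted | set(padding))
    for i in range(n_random):
        size = int(rng.integers(30, 90))
        sets[f"random_set_{i + 1:02d}"] = frozenset(rng.choice(universe, size=size, replace=False))
    return enrichment.GeneSetCollection(sets=sets, universe=frozenset(universe))


def run_all(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    simulate: bool = True,
    inputs: dict | None = None,
) -> dict:
    """Run the whole analysis; returns the report bundle as a dict.

    With ``simulate`` the inputs come from :func:`simulate_inputs` under
    ``config.seed``; otherwise pass a pre-loaded ``inputs`` dict with the
    same keys. When ``out_dir`` is given every stage's table plus a
    ``summary.json`` is written there.
    """
    config = config or PipelineConfig()
    seed = config.seed
    if simulate:
        inputs = simulate_inputs(config, seed)
    elif inputs is None:
        raise ValueError("need inputs when simulate=False")

    counts: CountMatrix = inputs["counts"]
    metadata: pd.DataFrame = inputs["metadata"]
    annotation = inputs["annotation"]
    truth = inputs.get("truth")

    # --- outlier screening -------------------------------------------------
    marker = "yki" if "yki" in counts.gene_ids else None
    flagged: list[str] = []
    if marker is not None:
        flagged = de.flag_outlier_controls(
            counts, metadata, marker_gene=marker, k=config.outlier_mad_k
        )

    # --- differential expression ------------------------------------------
    de_results: dict[str, de.DEResult] = {}
    de_counts = {}
    for name in CONTRAST_SPECS:
        res = run_contrast(counts, metadata, name, config.de_alpha, exclude_samples=flagged)
        de_results[name] = res
        up, down = res.up_down_counts()
        de_counts[name] = {"n_significant": up + down, "n_up": up, "n_down": down}

    # --- PCA ---------------------------------------------------------------
    vst = de.vst_transform(counts)
    pca_res = tx.pca(vst)
    attribution = {
        factor: tx.factor_variance_attribution(pca_res.scores, metadata, factor)
        for factor in ("cell_type", "stage", "genotype")
    }

    # --- concordance -------------------------------------------------------
    overlap = {}
    for label, (a, b) in {
        "germ": ("germ_hpo", "germ_yki"),
        "soma": ("soma_hpo", "soma_yki"),
    }.items():
        part = tx.classify_de_overlap(de_results[a], de_results[b])
        raw, rounded = (math.nan, None)
        if len(part.union):
            raw, rounded = tx.shared_fraction(
                part, include_opposite=config.include_opposite_in_shared
            )
        overlap[label] = {
            **part.counts(),
            "shared_fraction_raw": raw,
            "shared_fraction_pct": rounded,
        }
    excess = {}
    for name, c in de_counts.items():
        if c["n_down"] > 0:
            excess[name] = tx.updown_excess(c["n_up"], c["n_down"])

    # --- enrichment --------------------------------------------------------
    enrich_table = None
    enrich_summary = {}
    if truth is not None and "class" in truth.columns:
        collection = _synthetic_collection(counts.gene_ids, truth, seed + _SEED_SETS)
        part = tx.classify_de_overlap(de_results["germ_hpo"], de_results["germ_yki"])
        query = part.shared_up | part.shared_down
        if query:
            enrich_table = enrichment.hypergeom_enrich(
                query,
                collection,
                min_set_size=config.go_min_set_size,
                padj_cutoff=config.go_padj_cutoff,
            )
            enrich_summary = {
                "n_sets_tested": int(len(enrich_table)),
                "n_enriched": int(enrich_table["enriched"].sum()),
                "top_set": enrich_table.iloc[0]["set_name"] if len(enrich_table) else None,
            }

    # --- peak annotation ---------------------------------------------------
    peak_summaries = {}
    target_sets = []
    for name, ps in inputs["peak_sets"].items():
        assign = pk.assign_promoter(
            ps, annotation, flank=config.promoter_flank, mode=config.flank_mode
        )
        peak_summaries[name] = assign.summary()
        target_sets.append(assign.target_genes)
    intersection = pk.target_sets_intersection(target_sets).counts()
    common_targets = pk.target_sets_intersection(target_sets).common_to_all

    # --- network -----------------------------------------------------------
    chip = [
        (
            pd.DataFrame({"source": "yki", "target": sorted(common_targets)}),
            "chip-yki",
        )
    ] if common_targets else None
    net, net_summary = regnet.build_network(
        inputs["tf_edges"], inputs["ppi_edges"], chip_edges=chip
    )
    connector = regnet.enumerate_connectors(
        net, "hpo", "yki", max_paths=config.max_shortest_paths
    )
    target_stats = {
        name: regnet.target_overlap_stats(de_results[name], common_targets)
        for name in ("germ_hpo", "germ_yki")
    }

    summary = {
        "config": {
            "de_alpha": config.de_alpha,
            "promoter_flank": config.promoter_flank,
            "flank_mode": config.flank_mode,
            "go_min_set_size": config.go_min_set_size,
            "go_padj_cutoff": config.go_padj_cutoff,
            "kegg_padj_cutoff": config.kegg_padj_cutoff,
            "outlier_mad_k": config.outlier_mad_k,
            "seed": seed,
        },
        "n_libraries": len(counts.sample_ids),
        "flagged_outlier_controls": flagged,
        "de_counts": de_counts,
        "pca_variance_fraction": pca_res.variance_fraction.head(5),
        "pca_factor_r2_pc1": {f: float(s.iloc[0]) for f, s in attribution.items()},
        "overlap": overlap,
        "updown_excess_pct": excess,
        "enrichment": enrich_summary,
        "peak_promoter": peak_summaries,
        "target_intersection": intersection,
        "network": net_summary,
        "connector": {
            "length": connector["length"],
            "connectors": connector["connectors"],
            "unique": connector["unique"],
            "n_paths": connector["n_paths"],
        },
        "yki_target_overlap": target_stats,
    }

    bundle = {
        "summary": summary,
        "de_results": de_results,
        "pca": pca_res,
        "attribution": attribution,
        "enrichment_table": enrich_table,
        "network": net,
        "inputs": inputs,
    }

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = bundle["inputs"]
    write_counts(inputs["counts"], out_dir / "counts.tsv")
    write_metadata(inputs["metadata"], out_dir / "metadata.tsv")
    write_gtf(inputs["annotation"], out_dir / "annotation.gtf")
    for name, ps in inputs["peak_sets"].items():
        write_bed(ps, out_dir / f"peaks_{name}.bed")
    write_edges(inputs["tf_edges"], out_dir / "edges_tfgene.tsv")
    write_edges(inputs["ppi_edges"], out_dir / "edges_ppi.tsv")
    if inputs.get("truth") is not None:
        inputs["truth"].rename_axis("gene_id").to_csv(out_dir / "truth.tsv", sep="\t")
    for name, res in bundle["de_results"].items():
        res.table.to_csv(out_dir / f"de_{name}.tsv", sep="\t")
    bundle["pca"].scores.rename_axis("sample_id").to_csv(out_dir / "pca_scores.tsv", sep="\t")
    bundle["pca"].variance_fraction.rename_axis("component").to_csv(
        out_dir / "pca_variance.tsv", sep="\t"
    )
    if bundle["enrichment_table"] is not None:
        bundle["enrichment_table"].to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    bundle["network"].to_edge_frame().to_csv(out_dir / "network_edges.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_jsonify(bundle["summary"]), fh, indent=2, sort_keys=True)
        fh.write("\n")
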