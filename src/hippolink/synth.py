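"""Synthetic data with planted ground truth.

Every downstream stage of the pipeline is exercised on data generated here:
a 48-library bulk RNA-seq count matrix over two sorted ovary cell populations
(germ line / soma), three larval stages and three genotypes (control,
*hpo* RNAi, *yki* RNAi); a gene annotation; ChIP-seq-like peak sets with a
controllable promoter-overlap fraction; and a heterogeneous regulatory
network carrying a planted hpo--chinmo--yki motif.

The default count design emulates the structure of the study system:

* a dominant cell-type effect (germ vs soma) that should dominate PC1,
* a developmental-stage effect restricted to the soma,
* knockdown responses that are concordant between *hpo* and *yki* RNAi in the
  germ line but mostly genotype-exclusive in the soma, with small "opposite"
  classes (1 germ gene, 4 soma genes),
* negative-binomial noise with variance mu + alpha*mu^2,
* marker genes named ``hpo``, ``yki`` and ``chinmo`` with the qualitative
  self- and cross-knockdown responses observed in the study, and
* one plantable outlier: a mid-stage germ control library whose ``yki``
  expectation is multiplied by 0.1 (an "anomalously low marker" control).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CELL_TYPES,
    GENOTYPES,
    STAGES,
    CountMatrix,
    GeneAnnotation,
    PeakSet,
    validate_metadata,
)

CONTRASTS = ("germ_hpo", "germ_yki", "soma_hpo", "soma_yki")
CLASSES = ("null", "germ_shared", "germ_opposite", "soma_exclusive", "soma_opposite", "marker")

MOTIF_NODES = ("hpo", "chinmo", "yki")


class CapacityError(ValueError):
    """Requested objects cannot be packed into the available space."""


class GenerationError(RuntimeError):
    """Constrained random generation failed within the retry budget."""


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------


def default_replicate_map(include_early_germ_knockdowns: bool = False) -> dict:
    """The 48-library default design.

    Soma: 3 stages x 3 genotypes x 3 replicates = 27. Germ: controls at all 3
    stages x 3 replicates = 9; knockdowns at mid/late only, 2 genotypes x 2
    stages x 3 replicates = 12. Total 48. The early-germ knockdown libraries
    exist in the study as single replicates excluded from differential
    expression; pass ``include_early_germ_knockdowns=True`` to generate them
    too (one replicate each, total 50).
    """
    reps: dict[tuple[str, str, str], int] = {}
    for stage, genotype in itertools.product(STAGES, GENOTYPES):
        reps[("soma", stage, genotype)] = 3
    for stage in STAGES:
        reps[("germ", stage, "control")] = 3
    for stage in ("mid", "late"):
        for genotype in ("hpo_RNAi", "yki_RNAi"):
            reps[("germ", stage, genotype)] = 3
    for genotype in ("hpo_RNAi", "yki_RNAi"):
        reps[("germ", "early", genotype)] = 1 if include_early_germ_knockdowns else 0
    return reps


@dataclass
class DesignSpec:
    """Factor levels, per-condition replicate counts and library scale."""

    replicate_map: dict = field(default_factory=default_replicate_map)
    n_genes: int = 2000
    library_size: float = 2.0e5

    def __post_init__(self) -> None:
        for cond, n in self.replicate_map.items():
            cell_type, stage, genotype = cond
            if cell_type not in CELL_TYPES or stage not in STAGES or genotype not in GENOTYPES:
                raise ValueError(f"unknown condition {cond!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ValueError(f"replicate count for {cond!r} must be a non-negative int")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")

    @property
    def n_libraries(self) -> int:
        return int(sum(self.replicate_map.values()))

    def metadata(self) -> pd.DataFrame:
        """Expand the replicate map into a per-sample metadata table."""
        rows = []
        for (cell_type, stage, genotype), n in sorted(self.replicate_map.items()):
            for rep in range(1, n + 1):
                sid = f"{cell_type}_{stage}_{genotype}_r{rep}"
                rows.append((sid, cell_type, stage, genotype, rep))
        meta = pd.DataFrame(
            rows, columns=["sample_id", "cell_type", "stage", "genotype", "replicate"]
        ).set_index("sample_id")
        return validate_metadata(meta)


@dataclass
class EffectSpec:
    """Planted-effect sizes and class counts for :func:`make_counts`."""

    n_germ_shared: int = 250
    n_germ_opposite: int = 1
    n_soma_exclusive: int = 120  # per knockdown genotype
    n_soma_opposite: int = 4
    lfc_magnitude: float = 2.0
    dispersion: float = 0.05
    frac_celltype: float = 0.30
    celltype_sd: float = 2.0
    frac_stage_soma: float = 0.15
    stage_sd: float = 1.0
    marker_genes: bool = True
    outlier_factor: float | None = 0.1  # None disables the planted outlier

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("n_germ_shared", "n_germ_opposite", "n_soma_exclusive", "n_soma_opposite"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.lfc_magnitude):
            raise ValueError("lfc_magnitude must be finite")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def make_annotation(
    n_genes: int,
    n_chroms: int = 3,
    chrom_length: int = 5_000_000,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    min_len: int = 500,
    max_len: int = 3000,
) -> GeneAnnotation:
    """Place ``n_genes`` non-overlapping genes on ``n_chroms`` chromosomes.

    Gene lengths are uniform on [min_len, max_len]; leftover space is spread
    randomly into inter-gene gaps. Strands are random. Raises
    :class:`CapacityError` when the genes cannot fit.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_ids is not None and len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    rows = []
    gi = 0
    for ci, k in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        if k == 0:
            continue
        lengths = rng.integers(min_len, max_len + 1, size=k)
        slack = chrom_length - int(lengths.sum())
        if slack < 0:
            raise CapacityError(
                f"{k} genes of total length {int(lengths.sum())} exceed "
                f"chromosome length {chrom_length} on {chrom}"
            )
        # split slack into k+1 gaps (before, between, after)
        gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((gene_ids[gi], chrom, start, end, strand))
            pos = end
            gi += 1
    return GeneAnnotation(pd.DataFrame(rows, columns=list(GeneAnnotation.REQUIRED)))


# ---------------------------------------------------------------------------
# Counts with planted truth
# ---------------------------------------------------------------------------


def _assign_classes(n_genes: int, eff: EffectSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Build a truth table skeleton: one class per gene, true LFC per contrast."""
    n_marker = 3 if eff.marker_genes else 0
    n_random = n_genes - n_marker
    needed = (
        eff.n_germ_shared
        + eff.n_germ_opposite
        + 2 * eff.n_soma_exclusive
        + eff.n_soma_opposite
    )
    if needed > n_random:
        raise ValueError(
            f"planted classes need {needed} genes but only {n_random} are available"
        )
    gene_ids = [f"g{i:05d}" for i in range(1, n_random + 1)]
    if eff.marker_genes:
        gene_ids = list(MOTIF_NODES) + gene_ids

    truth = pd.DataFrame(
        0.0, index=pd.Index(gene_ids, name="gene_id"), columns=list(CONTRASTS)
    )
    truth["class"] = "null"
    truth["dispersion"] = eff.dispersion

    if eff.marker_genes:
        # hpo: strongly self-knocked-down in both cell types; yki: self-knocked
        # down, plus a weaker germ-line response to hpo RNAi (the study's
        # cross-regulation signal); chinmo: unaffected.
        truth.loc["hpo", ["germ_hpo", "soma_hpo"]] = -4.1
        truth.loc["yki", ["germ_yki", "soma_yki"]] = -1.5
        truth.loc["yki", "germ_hpo"] = -0.8
        truth.loc[["hpo", "yki"], "class"] = "marker"
        truth.loc["chinmo", "class"] = "marker"

    pool = iter(gene_ids[n_marker:])

    def take(n):
        return [next(pool) for _ in range(n)]

    mag = eff.lfc_magnitude
    g_shared = take(eff.n_germ_shared)
    signs = rng.choice([-1.0, 1.0], size=len(g_shared), p=[0.7, 0.3])  # down-biased
    truth.loc[g_shared, "germ_hpo"] = signs * mag
    truth.loc[g_shared, "germ_yki"] = signs * mag
    truth.loc[g_shared, "class"] = "germ_shared"

    g_opp = take(eff.n_germ_opposite)
    truth.loc[g_opp, "germ_hpo"] = -mag
    truth.loc[g_opp, "germ_yki"] = mag
    truth.loc[g_opp, "class"] = "germ_opposite"

    for contrast in ("soma_hpo", "soma_yki"):
        g_excl = take(eff.n_soma_exclusive)
        signs = rng.choice([-1.0, 1.0], size=len(g_excl))
        truth.loc[g_excl, contrast] = signs * mag
        truth.loc[g_excl, "class"] = "soma_exclusive"

    s_opp = take(eff.n_soma_opposite)
    truth.loc[s_opp, "soma_hpo"] = mag
    truth.loc[s_opp, "soma_yki"] = -mag
    truth.loc[s_opp, "class"] = "soma_opposite"
    return truth


def make_counts(
    design: DesignSpec | None = None,
    effects: EffectSpec | pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a count matrix under the design with planted effects.

    Returns ``(counts, metadata, truth)``. ``truth`` carries per-gene true
    log2 fold-changes for the four knockdown contrasts, the concordance
    class, the dispersion, and bookkeeping columns (``outlier_sample`` /
    ``outlier_marker`` as DataFrame attrs when an outlier was planted).

    Counts are negative binomial with mean
    ``baseline_g * sizefactor_j * 2**(sum of planted effects)`` and variance
    ``mu + dispersion * mu**2``; dispersion 0 falls back to Poisson.
    """
    design = design or DesignSpec()
    rng = np.random.default_rng(seed)
    meta = design.metadata()
    n_samples = len(meta)
    if n_samples == 0:
        raise ValueError("design has no libraries")

    if effects is None:
        effects = EffectSpec()
    if isinstance(effects, pd.DataFrame):
        # an explicit truth table fully determines the planted structure:
        # no latent cell-type/stage effects, no marker genes, no outlier
        truth = effects.copy()
        eff = EffectSpec(
            marker_genes=False, outlier_factor=None,
            frac_celltype=0.0, frac_stage_soma=0.0,
        )
        if len(truth) != design.n_genes:
            raise ValueError("truth table length must equal design.n_genes")
    else:
        eff = effects
        truth = _assign_classes(design.n_genes, eff, rng)

    n_genes = len(truth)
    gene_ids = truth.index.to_numpy()

    # baseline expression: lognormal, rescaled to the expected library size
    base = rng.lognormal(mean=1.0, sigma=1.2, size=n_genes)
    base *= design.library_size / base.sum()
    base = np.maximum(base, 0.05)
    if eff.marker_genes:
        # the pathway genes are robustly expressed in both cell populations
        marker_floor = 0.002 * design.library_size
        for g in MOTIF_NODES:
            gi = int(np.flatnonzero(gene_ids == g)[0])
            base[gi] = max(base[gi], marker_floor)

    size_factors = rng.lognormal(mean=0.0, sigma=0.15, size=n_samples)

    cell_type = meta["cell_type"].to_numpy()
    stage_idx = meta["stage"].map({"early": 0.0, "mid": 1.0, "late": 2.0}).to_numpy()
    genotype = meta["genotype"].to_numpy()
    is_soma = cell_type == "soma"

    # latent cell-type and soma-stage effects (not part of the contrast truth)
    n_marker = 3 if eff.marker_genes else 0
    latent_pool = np.arange(n_marker, n_genes)  # markers carry no latent effects
    n_ct = min(int(round(eff.frac_celltype * n_genes)), len(latent_pool))
    ct_effect = np.zeros(n_genes)
    idx_ct = rng.choice(latent_pool, size=n_ct, replace=False)
    ct_effect[idx_ct] = rng.normal(0.0, eff.celltype_sd, size=n_ct)
    n_st = min(int(round(eff.frac_stage_soma * n_genes)), len(latent_pool))
    st_effect = np.zeros(n_genes)
    idx_st = rng.choice(latent_pool, size=n_st, replace=False)
    st_effect[idx_st] = rng.normal(0.0, eff.stage_sd, size=n_st)

    lfc = {c: truth[c].to_numpy() for c in CONTRASTS}

    log2mu = np.zeros((n_genes, n_samples))
    log2mu += ct_effect[:, None] * is_soma[None, :]
    log2mu += st_effect[:, None] * (stage_idx * is_soma)[None, :]
    for j in range(n_samples):
        if genotype[j] == "hpo_RNAi":
            log2mu[:, j] += lfc["soma_hpo" if is_soma[j] else "germ_hpo"]
        elif genotype[j] == "yki_RNAi":
            log2mu[:, j] += lfc["soma_yki" if is_soma[j] else "germ_yki"]

    mu = base[:, None] * size_factors[None, :] * np.exp2(log2mu)

    outlier_sample = outlier_marker = None
    if eff.outlier_factor is not None and eff.marker_genes:
        candidates = meta.index[
            (meta.cell_type == "germ") & (meta.stage == "mid") & (meta.genotype == "control")
        ]
        if len(candidates) > 0:
            outlier_sample = candidates[0]
            outlier_marker = "yki"
            gi = int(np.flatnonzero(gene_ids == outlier_marker)[0])
            sj = int(meta.index.get_loc(outlier_sample))
            mu[gi, sj] *= eff.outlier_factor

    alpha = truth["dispersion"].to_numpy()[:, None]
    counts = np.empty_like(mu, dtype=np.int64)
    poisson = alpha[:, 0] <= 0
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mu[nb])
        counts[nb] = rng.negative_binomial(r, p)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=meta.index))
    truth = truth.copy()
    truth.attrs["outlier_sample"] = outlier_sample
    truth.attrs["outlier_marker"] = outlier_marker
    return cm, meta, truth


# ---------------------------------------------------------------------------
# ChIP-seq-like peaks
# ---------------------------------------------------------------------------


def make_peaks(
    annotation: GeneAnnotation,
    n_peaks: int,
    promoter_fraction: float = 0.72,
    flank: int = 1500,
    peak_width: int = 200,
    seed: int = 0,
    chrom_length: int | None = None,
    name_prefix: str = "peak",
) -> PeakSet:
    """Place peaks so that ~``promoter_fraction`` overlap a TSS +/- flank window.

    Each peak is independently promoter-targeted with probability
    ``promoter_fraction`` (so the realised fraction is Binomial). Promoter
    peaks are placed to overlap a randomly chosen gene's window; the rest are
    rejection-sampled to avoid every window. Deterministic under seed.
    """
    if not (0.0 <= promoter_fraction <= 1.0):
        raise ValueError("promoter_fraction must lie in [0, 1]")
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if n_peaks == 0:
        return PeakSet(pd.DataFrame(columns=["peak_id", "chrom", "start", "end", "score"]))

    rng = np.random.default_rng(seed)
    genes = annotation.genes
    tss = annotation.tss.to_numpy()
    chroms = genes["chrom"].to_numpy()
    if chrom_length is None:
        chrom_length = int(genes["end"].max() + 10 * (flank + peak_width))

    # promoter windows per chromosome, 0-based half-open [tss-flank, tss+flank+1)
    windows: dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        t = tss[chroms == c]
        w = np.stack([np.maximum(t - flank, 0), t + flank + 1], axis=1)
        windows[c] = w[np.argsort(w[:, 0])]

    def overlaps_any(c: str, s: int, e: int) -> bool:
        w = windows.get(c)
        if w is None:
            return False
        return bool(np.any((w[:, 0] < e) & (s < w[:, 1])))

    all_chroms = sorted(windows)
    rows = []
    is_prom = rng.random(n_peaks) < promoter_fraction
    for i in range(n_peaks):
        if is_prom[i]:
            gi = int(rng.integers(len(genes)))
            c = chroms[gi]
            t = int(tss[gi])
            lo = max(t - flank - peak_width + 1, 0)
            hi = t + flank  # start <= tss+flank guarantees overlap of [tss-flank, tss+flank+1)
            s = int(rng.integers(lo, hi + 1))
        else:
            for attempt in range(1000):
                c = all_chroms[int(rng.integers(len(all_chroms)))]
                s = int(rng.integers(0, max(chrom_length - peak_width, 1)))
                if not overlaps_any(c, s, s + peak_width):
                    break
            else:
                raise CapacityError(
                    "could not place a non-promoter peak; promoter windows cover the genome"
                )
        rows.append((f"{name_prefix}{i + 1:05d}", c, s, s + peak_width, 0.0))
    return PeakSet(pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "score"]))


# ---------------------------------------------------------------------------
# Regulatory network with a planted motif
# ---------------------------------------------------------------------------


def _motif_edges() -> tuple[pd.DataFrame, pd.DataFrame]:
    tf = pd.DataFrame(
        [
            ("chinmo", "yki", "tfgene", "droid-like"),
            ("chinmo", "hpo", "tfgene", "droid-like"),
            ("yki", "chinmo", "tfgene", "droid-like"),
        ],
        columns=["source", "target", "type", "provenance"],
    )
    ppi = pd.DataFrame(
        [("hpo", "chinmo", "ppi", "droid-like")],
        columns=["source", "target", "type", "provenance"],
    )
    return tf, ppi


def _violates_motif(tf_pairs: set, ppi_pairs: set) -> set:
    """Return the set of random edges creating a forbidden hpo->yki shortcut.

    Forbidden: any direct hpo--yki connection, and any two-arc path
    hpo -> X -> yki with X != chinmo. PPI pairs are undirected.
    """
    arcs = set(tf_pairs)
    for a, b in ppi_pairs:
        arcs.add((a, b))
        arcs.add((b, a))

    def origin(u, v):
        """Map an arc back to the stored random edge(s) that produced it."""
        out = set()
        if (u, v) in tf_pairs:
            out.add(("tfgene", u, v))
        if (u, v) in ppi_pairs:
            out.add(("ppi", u, v))
        if (v, u) in ppi_pairs:
            out.add(("ppi", v, u))
        return out

    bad = set()
    # no direct hpo--yki edge of any kind or direction
    for u, v in (("hpo", "yki"), ("yki", "hpo")):
        bad |= origin(u, v)
    # no two-arc hpo -> X -> yki shortcut except through chinmo
    mids = {v for (u, v) in arcs if u == "hpo"} & {u for (u, v) in arcs if v == "yki"}
    for x in mids - {"chinmo"}:
        bad |= origin("hpo", x)
        bad |= origin(x, "yki")
    return bad


def make_network(
    n_tfs: int = 20,
    n_genes: int = 100,
    n_tfgene_edges: int = 200,
    n_ppi_edges: int = 150,
    plant_motif: bool = True,
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random TF->gene and PPI edge lists, optionally with the planted motif.

    With ``plant_motif`` the output contains nodes hpo/chinmo/yki wired as
    ppi(hpo--chinmo), tfgene(chinmo->yki), tfgene(chinmo->hpo),
    tfgene(yki->chinmo), no direct hpo--yki edge, and — validated after
    generation, with offending random edges redrawn — no other hpo->yki path
    of length <= 2. Edge counts refer to the random (non-motif) edges and are
    exact after deduplication.
    """
    rng = np.random.default_rng(seed)
    tf_nodes = [f"tf{i:03d}" for i in range(1, n_tfs + 1)]
    gene_nodes = [f"gene{i:03d}" for i in range(1, n_genes + 1)]
    all_nodes = tf_nodes + gene_nodes
    if plant_motif:
        all_nodes = all_nodes + list(MOTIF_NODES)
        tf_pool = tf_nodes + ["chinmo", "yki"]
    else:
        tf_pool = tf_nodes

    max_tf = len(tf_pool) * max(len(all_nodes) - 1, 0)
    max_ppi = len(all_nodes) * (len(all_nodes) - 1) // 2
    if n_tfgene_edges > max_tf or n_ppi_edges > max_ppi:
        raise CapacityError(
            f"requested {n_tfgene_edges} tfgene / {n_ppi_edges} ppi edges exceed "
            f"capacity {max_tf} / {max_ppi}"
        )

    def draw_tf(exclude: set) -> tuple:
        for _ in range(10000):
            s = tf_pool[int(rng.integers(len(tf_pool)))]
            t = all_nodes[int(rng.integers(len(all_nodes)))]
            if s != t and (s, t) not in exclude:
                return (s, t)
        raise GenerationError("could not draw a fresh tfgene edge")

    def draw_ppi(exclude: set) -> tuple:
        for _ in range(10000):
            a = all_nodes[int(rng.integers(len(all_nodes)))]
            b = all_nodes[int(rng.integers(len(all_nodes)))]
            if a == b:
                continue
            pair = tuple(sorted((a, b)))
            if pair not in exclude:
                return pair
        raise GenerationError("could not draw a fresh ppi edge")

    motif_tf, motif_ppi = _motif_edges() if plant_motif else (None, None)
    motif_tf_pairs = set(map(tuple, motif_tf[["source", "target"]].to_numpy())) if plant_motif else set()
    motif_ppi_pairs = {tuple(sorted(p)) for p in motif_ppi[["source", "target"]].to_numpy()} if plant_motif else set()

    tf_pairs: set = set()
    while len(tf_pairs) < n_tfgene_edges:
        tf_pairs.add(draw_tf(tf_pairs | motif_tf_pairs))
    ppi_pairs: set = set()
    while len(ppi_pairs) < n_ppi_edges:
        ppi_pairs.add(draw_ppi(ppi_pairs | motif_ppi_pairs))

    if plant_motif:
        for _ in range(max_retries):
            bad = _violates_motif(tf_pairs, ppi_pairs)
            if not bad:
                break
            for kind, u, v in bad:
                if kind == "tfgene":
                    tf_pairs.discard((u, v))
                else:
                    ppi_pairs.discard(tuple(sorted((u, v))))
            while len(tf_pairs) < n_tfgene_edges:
                tf_pairs.add(draw_tf(tf_pairs | motif_tf_pairs))
            while len(ppi_pairs) < n_ppi_edges:
                ppi_pairs.add(draw_ppi(ppi_pairs | motif_ppi_pairs))
        else:
            raise GenerationError(
                f"motif validation failed after {max_retries} regeneration rounds"
            )

    tf_df = pd.DataFrame(sorted(tf_pairs), columns=["source", "target"])
    tf_df["type"] = "tfgene"
    tf_df["provenance"] = "droid-like"
    ppi_df = pd.DataFrame(sorted(ppi_pairs), columns=["source", "target"])
    ppi_df["type"] = "ppi"
    ppi_df["provenance"] = "droid-like"
    if plant_motif:
        tf_df = pd.concat([motif_tf, tf_df], ignore_index=True)
        ppi_df = pd.concat([motif_ppi, ppi_df], ignore_index=True)
    return tf_df, ppi_df
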