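"""On-disk formats and in-memory containers; the coordinate-convention anchor.

Every module in the package consumes 0-based half-open intervals. GTF is the
single 1-based closed surface: coordinates are converted on read and converted
back on write, nowhere else. Parsers validate and reject malformed input with
the offending line number rather than silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger("hippolink")

VALID_STRANDS = frozenset({"+", "-"})
EDGE_TYPES = frozenset({"tfgene", "ppi"})


class ParseError(ValueError):
    """Malformed on-disk input; carries the file and 1-based line number."""

    def __init__(self, path, lineno: int | None, msg: str):
        where = f"{path}" if lineno is None else f"{path}:{lineno}"
        super().__init__(f"{where}: {msg}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix.

    ``data`` is a genes-by-samples DataFrame with unique string gene IDs as
    index and unique string sample IDs as columns; all entries are
    non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("counts must be finite and non-negative")
        if np.any(arr != np.floor(arr)):
            raise ValueError("counts must be integral")
        self.data = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(sample_ids)].copy())


@dataclass
class GeneAnnotation:
    """Gene models: unique IDs, chrom, 0-based half-open [start, end), strand.

    The transcription start site (TSS) is derived, never stored: ``start`` on
    the + strand and ``end - 1`` on the - strand (the last base of the
    half-open interval).
    """

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        df = self.genes
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        bad_strand = ~df["strand"].isin(VALID_STRANDS)
        if bad_strand.any():
            raise ValueError(
                f"invalid strand values: {df.loc[bad_strand, 'strand'].unique().tolist()}"
            )
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
            raise ValueError(f"start >= end for genes: {bad[:5]}")
        df = df.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.genes = df

    @property
    def tss(self) -> pd.Series:
        """Per-gene TSS position (0-based), indexed by gene_id."""
        g = self.genes
        pos = np.where(g["strand"].to_numpy() == "+", g["start"], g["end"] - 1)
        return pd.Series(pos, index=g["gene_id"].to_numpy(), name="tss")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PeakSet:
    """ChIP-seq peak intervals: 0-based half-open, optional score."""

    peaks: pd.DataFrame  # columns: peak_id, chrom, start, end, score

    def __post_init__(self) -> None:
        df = self.peaks.copy()
        for c in ("peak_id", "chrom", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"peak table missing column {c!r}")
        if "score" not in df.columns:
            df["score"] = 0.0
        if df["peak_id"].duplicated().any():
            raise ValueError("duplicate peak IDs")
        if (df["start"] >= df["end"]).any():
            raise ValueError("peak start >= end")
        df = df.loc[:, ["peak_id", "chrom", "start", "end", "score"]].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.peaks = df

    def __len__(self) -> int:
        return len(self.peaks)


METADATA_FACTORS = ("cell_type", "stage", "genotype", "replicate")
CELL_TYPES = ("germ", "soma")
STAGES = ("early", "mid", "late")
GENOTYPES = ("control", "hpo_RNAi", "yki_RNAi")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table (index = sample IDs) and return a copy."""
    missing = [c for c in METADATA_FACTORS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample IDs in metadata")
    bad = set(meta["cell_type"]) - set(CELL_TYPES)
    if bad:
        raise ValueError(f"unknown cell_type levels: {sorted(bad)}")
    bad = set(meta["stage"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage levels: {sorted(bad)}")
    bad = set(meta["genotype"]) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotype levels: {sorted(bad)}")
    return meta.copy()


# ---------------------------------------------------------------------------
# Count matrix and metadata TSV
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV (header row = sample IDs, first col = gene)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises many flavours
        raise ParseError(path, None, f"cannot parse count TSV: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return CountMatrix(df)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.data.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_mtx(mtx_path, genes_path, samples_path) -> CountMatrix:
    """Read a MatrixMarket triplet plus one-ID-per-line gene/sample files."""
    mat = mmread(mtx_path)
    genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
    samples = [ln.strip() for ln in open(samples_path) if ln.strip()]
    arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if arr.shape != (len(genes), len(samples)):
        raise ParseError(
            mtx_path, None,
            f"matrix shape {arr.shape} does not match {len(genes)} genes x {len(samples)} samples",
        )
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def write_counts_mtx(cm: CountMatrix, mtx_path, genes_path, samples_path) -> None:
    mmwrite(str(mtx_path), coo_matrix(cm.values))
    Path(genes_path).write_text("".join(g + "\n" for g in cm.gene_ids))
    Path(samples_path).write_text("".join(s + "\n" for s in cm.sample_ids))


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    try:
        return validate_metadata(df)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GTF (the only 1-based closed surface)
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Read gene features from a GTF file.

    Only ``gene`` feature lines are consumed; each must carry a ``gene_id``
    attribute. 1-based closed [start, end] becomes 0-based half-open
    [start-1, end) internally.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start!r}, {end!r}") from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(path, lineno, f"invalid 1-based interval [{start_i}, {end_i}]")
            if strand not in VALID_STRANDS:
                raise ParseError(path, lineno, f"invalid or missing strand {strand!r}")
            gene_id = _gtf_attribute(attrs, "gene_id")
            if gene_id is None:
                raise ParseError(path, lineno, "missing gene_id attribute")
            rows.append((gene_id, chrom, start_i - 1, end_i, strand))
    df = pd.DataFrame(rows, columns=list(GeneAnnotation.REQUIRED))
    try:
        return GeneAnnotation(df)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from exc


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


def write_gtf(ann: GeneAnnotation, path: str | Path, source: str = "hippolink") -> None:
    with open(path, "w") as fh:
        for row in ann.genes.itertuples(index=False):
            fh.write(
                "\t".join(
                    (
                        row.chrom,
                        source,
                        "gene",
                        str(row.start + 1),  # back to 1-based closed
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        f'gene_id "{row.gene_id}";',
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 (native 0-based half-open)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> PeakSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >= 4 BED fields, got {len(fields)}")
            chrom, start, end, name = fields[:4]
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start!r}, {end!r}") from None
            if start_i < 0 or end_i <= start_i:
                raise ParseError(path, lineno, f"invalid interval [{start_i}, {end_i})")
            rows.append((name, chrom, start_i, end_i, score))
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "score"])
    try:
        return PeakSet(df)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_bed(ps: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in ps.peaks.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_id}\t{row.score:g}\t.\n"
            )


# ---------------------------------------------------------------------------
# Typed edge lists
# ---------------------------------------------------------------------------


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a typed edge list TSV: source, target, type, provenance."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(path, None, f"cannot parse edge TSV: {exc}") from exc
    required = ["source", "target", "type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, None, f"edge list missing columns: {missing}")
    if "provenance" not in df.columns:
        df["provenance"] = "user"
    bad = ~df["type"].isin(EDGE_TYPES)
    if bad.any():
        first = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header +1 1-based
        raise ParseError(path, first, f"invalid edge type {df.loc[bad, 'type'].iloc[0]!r}")
    if df[required].isna().any().any():
        raise ParseError(path, None, "edge list contains missing source/target/type values")
    return df.loc[:, ["source", "target", "type", "provenance"]].reset_index(drop=True)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.loc[:, ["source", "target", "type", "provenance"]].to_csv(
        path, sep="\t", index=False
    )


def setup_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr; verbosity 0=WARNING, 1=INFO, 2+=DEBUG."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
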