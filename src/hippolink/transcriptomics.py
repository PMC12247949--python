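"""Sample-level PCA and differential-expression concordance statistics.

PCA runs on per-gene-centered (unscaled) variance-stabilised expression, the
standard bulk-expression convention; per-component variance fractions are
computed over all components and sum to one. The concordance classifier
partitions two DE results into shared-up / shared-down / opposite /
exclusive sets — the Venn algebra behind statements like "51% of the
differentially expressed genes were common to both knockdowns" — and the
percentage helpers reproduce the derived statistics exactly from counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEResult


def _round_half_away(x: float, ndigits: int = 0) -> float:
    q = 10.0**ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: pd.Series  # over ALL components; sums to 1
    gene_means: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        """scores @ loadings.T + gene means (exact when all components kept)."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(
            rec.T + self.gene_means.to_numpy()[:, None],
            index=self.loadings.index,
            columns=self.scores.index,
        )


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a genes x samples expression matrix.

    Genes are centered across samples; no scaling. Signs are fixed by
    forcing the largest-magnitude loading of each component positive, so
    results are reproducible across runs and BLAS builds.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.to_numpy(float)
    gene_means = X.mean(axis=1)
    Xc = X - gene_means[:, None]
    if not np.any(np.abs(Xc) > 0):
        raise ValueError("matrix has zero variance; PCA undefined")
    # samples x genes orientation; components are right-singular vectors of M
    M = Xc.T
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k_all = len(s)
    k = k_all if n_components is None else min(n_components, k_all)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    # sign convention
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=comp),
        variance_fraction=pd.Series(
            frac, index=[f"PC{i + 1}" for i in range(k_all)], name="variance_fraction"
        ),
        gene_means=pd.Series(gene_means, index=matrix.index, name="gene_mean"),
    )


def factor_variance_attribution(
    scores: pd.DataFrame, metadata: pd.DataFrame, factor: str
) -> pd.Series:
    """Per-component R^2 of a metadata factor: between-group SS / total SS."""
    if factor not in metadata.columns:
        raise ValueError(f"unknown factor {factor!r}")
    labels = metadata.loc[scores.index, factor]
    out = {}
    for comp in scores.columns:
        y = scores[comp].to_numpy(float)
        total = np.sum((y - y.mean()) ** 2)
        if total == 0:
            out[comp] = 0.0
            continue
        between = 0.0
        for _, idx in labels.groupby(labels, observed=True).groups.items():
            yi = scores.loc[idx, comp].to_numpy(float)
            between += len(yi) * (yi.mean() - y.mean()) ** 2
        out[comp] = float(between / total)
    return pd.Series(out, name=f"R2_{factor}")


# ---------------------------------------------------------------------------
# DE-set concordance
# ---------------------------------------------------------------------------


@dataclass
class OverlapPartition:
    """Disjoint partition of the union of two significant gene sets.

    ``shared_up``/``shared_down``: significant in both with concordant sign;
    ``opposite``: significant in both with discordant sign; ``exclusive_a`` /
    ``exclusive_b``: significant in exactly one result.
    """

    shared_up: frozenset
    shared_down: frozenset
    opposite: frozenset
    exclusive_a: frozenset
    exclusive_b: frozenset

    def __post_init__(self) -> None:
        sets = [self.shared_up, self.shared_down, self.opposite, self.exclusive_a, self.exclusive_b]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise ValueError("partition sets are not pairwise disjoint")

    @property
    def union(self) -> frozenset:
        return frozenset(
            self.shared_up | self.shared_down | self.opposite | self.exclusive_a | self.exclusive_b
        )

    def counts(self) -> dict[str, int]:
        return {
            "shared_up": len(self.shared_up),
            "shared_down": len(self.shared_down),
            "opposite": len(self.opposite),
            "exclusive_a": len(self.exclusive_a),
            "exclusive_b": len(self.exclusive_b),
            "union": len(self.union),
        }


def classify_de_overlap(
    de_a: DEResult, de_b: DEResult, alpha: float | None = None
) -> OverlapPartition:
    """Partition two DE results over the same gene universe."""
    ua, ub = set(de_a.table.index), set(de_b.table.index)
    if ua != ub:
        raise ValueError(
            f"gene universes differ (symmetric difference of {len(ua ^ ub)} genes)"
        )

    def sig(de: DEResult) -> pd.DataFrame:
        t = de.table
        mask = (t["padj"] < alpha).fillna(False) if alpha is not None else t["significant"]
        return t[mask]

    a, b = sig(de_a), sig(de_b)
    both = a.index.intersection(b.index)
    sign_a = np.sign(a.loc[both, "log2FC"])
    sign_b = np.sign(b.loc[both, "log2FC"])
    concordant = both[(sign_a == sign_b).to_numpy()]
    return OverlapPartition(
        shared_up=frozenset(concordant[(a.loc[concordant, "log2FC"] > 0).to_numpy()]),
        shared_down=frozenset(concordant[(a.loc[concordant, "log2FC"] < 0).to_numpy()]),
        opposite=frozenset(both[(sign_a != sign_b).to_numpy()]),
        exclusive_a=frozenset(a.index.difference(b.index)),
        exclusive_b=frozenset(b.index.difference(a.index)),
    )


def shared_fraction(
    partition: OverlapPartition | None = None,
    *,
    n_sig_a: int | None = None,
    n_sig_b: int | None = None,
    n_shared_same: int | None = None,
    n_opposite: int = 0,
    include_opposite: bool = True,
) -> tuple[float, int]:
    """Percent of the significant-gene union common to both contrasts.

    Accepts either a computed :class:`OverlapPartition` or raw counts (the
    two significant-set sizes, the same-direction shared count and the
    opposite count). Genes significant in both but with opposite signs are
    counted as shared by default — they are differentially expressed under
    both conditions — with ``include_opposite=False`` available.

    Returns ``(raw_percent, rounded_percent)``; rounding is half away from
    zero to the nearest integer.
    """
    if partition is not None:
        counts = partition.counts()
        n_shared_same = counts["shared_up"] + counts["shared_down"]
        n_opposite = counts["opposite"]
        union = counts["union"]
    else:
        if n_sig_a is None or n_sig_b is None or n_shared_same is None:
            raise ValueError("need n_sig_a, n_sig_b and n_shared_same without a partition")
        union = n_sig_a + n_sig_b - n_shared_same - n_opposite
    if union == 0:
        raise ValueError("no significant genes in either contrast")
    shared = n_shared_same + (n_opposite if include_opposite else 0)
    raw = 100.0 * shared / union
    return raw, int(_round_half_away(raw))


def updown_excess(n_up: int, n_down: int) -> float:
    """Percent excess of upregulated over downregulated genes.

    100 * (n_up - n_down) / n_down, reported to one decimal (half away from
    zero). Undefined for n_down = 0.
    """
    if n_down <= 0:
        raise ValueError("updown_excess undefined for n_down = 0")
    return _round_half_away(100.0 * (n_up - n_down) / n_down, 1)
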