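"""Negative-binomial differential expression for bulk RNA-seq counts.

A deliberately compact NB Wald engine in the DESeq2 tradition:
median-of-ratios size factors, a ``log2(normalized + 1)``
variance-stabilising surrogate for PCA-stage work, gene-wise
method-of-moments dispersion with 50/50 shrinkage toward a fitted
mean--dispersion trend, per-gene iteratively-reweighted-least-squares fits of
a log-link NB regression with size-factor offsets, two-sided Wald tests, and
Benjamini-Hochberg adjustment. Trended/apeGLM shrinkage of fold-changes,
Cook's-distance filtering and independent filtering are intentionally not
replicated.

The NB parameterisation throughout is variance = mu + alpha * mu**2, alpha >= 0
(alpha = 0 is the Poisson limit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

logger = logging.getLogger("hippolink")

LN2 = np.log(2.0)
_MAX_BETA = 15.0  # natural-log scale; |log2FC| cap ~21.6
_IRLS_ITER = 50
_IRLS_TOL = 1e-8


@dataclass
class DEResult:
    """Per-gene differential-expression table for one contrast.

    Columns: baseMean, log2FC, SE, stat, pvalue, padj, significant.
    ``log2FC`` is level_A relative to level_B. Genes with all-zero counts
    get NaN p-values and are excluded from the BH adjustment.
    """

    table: pd.DataFrame
    contrast: tuple = ("", "", "")
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        ok = t["padj"].to_numpy()
        p = t["pvalue"].to_numpy()
        with np.errstate(invalid="ignore"):
            if np.any(ok[~np.isnan(ok)] > 1) or np.any(ok[~np.isnan(ok)] < 0):
                raise ValueError("padj outside [0, 1]")
            if np.any(ok < p - 1e-12):
                raise ValueError("padj must be >= pvalue")

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def up_down_counts(self) -> tuple[int, int]:
        sig = self.table[self.table["significant"]]
        return int((sig["log2FC"] > 0).sum()), int((sig["log2FC"] < 0).sum())


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples restricted to
    genes positive in every sample; each sample's factor is the median ratio
    of its counts to the reference. With a single sample the factor is 1 by
    convention. When no gene is positive everywhere, either raise (default)
    or, with ``allow_pseudo_reference``, fall back to a geometric mean over
    positive entries only.
    """
    y = counts.values.astype(float)
    n = y.shape[1]
    if n == 1:
        return pd.Series([1.0], index=counts.sample_ids, name="size_factor")
    all_pos = np.all(y > 0, axis=1)
    if not all_pos.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; pass "
                "allow_pseudo_reference=True to use a positive-entry geometric mean"
            )
        with np.errstate(divide="ignore"):
            logy = np.where(y > 0, np.log(y), np.nan)
        ref = np.exp(np.nanmean(logy, axis=1))
        keep = np.isfinite(ref) & (ref > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(y[keep] > 0, y[keep] / ref[keep, None], np.nan)
        sf = np.nanmedian(ratios, axis=0)
    else:
        ref = np.exp(np.mean(np.log(y[all_pos]), axis=1))
        sf = np.median(y[all_pos] / ref[:, None], axis=0)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factor estimation produced non-positive factors")
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def vst_transform(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Variance-stabilising surrogate: log2(count / size_factor + 1)."""
    if factors is None:
        factors = size_factors(counts)
    f = factors.reindex(counts.sample_ids).to_numpy()
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("size factors must be positive and cover all samples")
    return pd.DataFrame(
        np.log2(counts.values / f[None, :] + 1.0),
        index=counts.gene_ids,
        columns=counts.sample_ids,
    )


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


def estimate_dispersion(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    group_cols: tuple[str, ...] = ("cell_type", "stage", "genotype"),
    factors: pd.Series | None = None,
    trend_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion alpha.

    Method of moments on size-factor-normalized counts within replicate
    groups — alpha_hat = max(0, (s^2 - mbar) / mbar^2) pooled across groups by
    residual degrees of freedom — then shrunk ``trend_weight``/1-trend_weight
    toward a mean--dispersion trend a0 + a1/mu fitted across genes. When no
    group has >= 2 replicates the gene-wise moments are unavailable and a
    constant fallback dispersion (0.1) is returned with a warning.
    """
    if factors is None:
        factors = size_factors(counts)
    q = counts.values / factors.reindex(counts.sample_ids).to_numpy()[None, :]
    cols = [c for c in group_cols if c in metadata.columns]
    groups = metadata.loc[counts.sample_ids].groupby(list(cols), observed=True).groups
    n_genes = q.shape[0]

    num = np.zeros(n_genes)  # df-weighted sum of per-group alpha estimates
    den = 0.0
    any_replicated = False
    for _, idx in groups.items():
        cols_idx = [counts.sample_ids.index(s) for s in idx]
        if len(cols_idx) < 2:
            continue
        any_replicated = True
        sub = q[:, cols_idx]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, np.maximum(0.0, (s2 - m) / m**2), 0.0)
        df = len(cols_idx) - 1
        num += df * a
        den += df

    mu = q.mean(axis=1)
    if not any_replicated:
        logger.warning(
            "no replicated condition group: falling back to constant dispersion 0.1"
        )
        return pd.Series(0.1, index=counts.gene_ids, name="dispersion")

    a_gene = num / den
    # trend: alpha ~ a0 + a1 / mu, least squares over informative genes
    use = (mu > 0) & np.isfinite(a_gene)
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(X, a_gene[use], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:
        a0, a1 = float(np.median(a_gene[use])) if use.any() else 0.1, 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-8), a0)
    alpha = (1.0 - trend_weight) * a_gene + trend_weight * trend
    alpha = np.maximum(alpha, 0.0)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# NB Wald regression
# ---------------------------------------------------------------------------


def _nb_irls(
    y: np.ndarray,  # genes x samples
    X: np.ndarray,  # samples x p
    offset: np.ndarray,  # samples
    alpha: np.ndarray,  # genes
) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for log-link NB regression with fixed per-gene dispersion.

    Returns (beta: genes x p, cov: genes x p x p). Score equations are those
    of the NB2 log-link GLM; weights w = mu / (1 + alpha * mu).
    """
    G, n = y.shape
    p = X.shape[1]
    # initialise: intercept at log of mean normalized count, slopes 0
    qbar = np.maximum((y / np.exp(offset)[None, :]).mean(axis=1), 1e-8)
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(qbar)
    eps = 1e-10
    for _ in range(_IRLS_ITER):
        eta = offset[None, :] + beta @ X.T
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / np.maximum(mu, eps)
        XtWX = np.einsum("np,gn,nq->gpq", X, w, X, optimize=True)
        XtWz = np.einsum("np,gn,gn->gp", X, w, z, optimize=True)
        XtWX += 1e-8 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        new = np.clip(new, -_MAX_BETA, _MAX_BETA)
        delta = np.max(np.abs(new - beta), axis=1)
        beta = new
        if np.all(delta < _IRLS_TOL):
            break
    eta = np.clip(offset[None, :] + beta @ X.T, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, w, X, optimize=True)
    XtWX += 1e-8 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(XtWX)
    return beta, cov


def _design_matrix(
    meta: pd.DataFrame, factor: str, level_a: str, level_b: str, covariates: list[str]
) -> tuple[np.ndarray, int, list[str]]:
    """Intercept + A-vs-B indicator + treatment-coded covariates."""
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["intercept"]
    cols.append((meta[factor] == level_a).to_numpy(float))
    names.append(f"{factor}_{level_a}_vs_{level_b}")
    contrast_idx = 1
    for cov in covariates:
        levels = sorted(meta[cov].astype(str).unique())
        for lv in levels[1:]:
            cols.append((meta[cov].astype(str) == lv).to_numpy(float))
            names.append(f"{cov}_{lv}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix is not full rank; factors {[factor] + covariates} are confounded"
        )
    return X, contrast_idx, names


def wald_de(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    contrast: tuple[str, str, str],
    alpha: float = 0.05,
    covariates: list[str] | None = None,
    factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    exclude_samples: list[str] | None = None,
) -> DEResult:
    """Per-gene NB Wald test for ``contrast = (factor, level_A, level_B)``.

    Samples are restricted to the two contrast levels (after removing
    ``exclude_samples``); ``covariates`` (e.g. ``["stage"]``) are adjusted
    for with treatment coding. log2FC > 0 means higher expression in
    level_A. Genes with all-zero counts in the subset receive NaN
    p-values and do not enter the BH adjustment.
    """
    factor, level_a, level_b = contrast
    if factor not in metadata.columns:
        raise ValueError(f"unknown contrast factor {factor!r}")
    covariates = covariates or []
    meta = metadata.loc[counts.sample_ids]
    if exclude_samples:
        meta = meta.drop(index=list(exclude_samples), errors="ignore")
    for lv in (level_a, level_b):
        if (meta[factor] == lv).sum() < 1:
            raise ValueError(f"contrast level {lv!r} has no samples")
    keep = meta[factor].isin([level_a, level_b])
    meta = meta[keep]
    cm = counts.subset_samples(list(meta.index))

    if factors is None:
        factors = size_factors(cm)
    factors = factors.reindex(cm.sample_ids)
    if dispersion is None:
        dispersion = estimate_dispersion(cm, meta, group_cols=tuple([factor] + covariates), factors=factors)
    disp = dispersion.reindex(cm.gene_ids).to_numpy()

    X, ci, _names = _design_matrix(meta, factor, level_a, level_b, covariates)
    y = cm.values.astype(float)
    offset = np.log(factors.to_numpy())

    nonzero = y.sum(axis=1) > 0
    beta = np.full((y.shape[0], X.shape[1]), np.nan)
    se = np.full(y.shape[0], np.nan)
    if nonzero.any():
        b, cov = _nb_irls(y[nonzero], X, offset, disp[nonzero])
        beta[nonzero] = b
        se_ln = np.sqrt(np.maximum(cov[:, ci, ci], 0.0))
        se[nonzero] = se_ln

    log2fc = beta[:, ci] / LN2
    se2 = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, beta[:, ci] / se, np.nan)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(np.isnan(stat), np.nan, pvalue)
    padj = bh_adjust(pvalue)

    base_mean = (y / np.exp(offset)[None, :]).mean(axis=1)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "SE": se2,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )
    table["significant"] = (table["padj"] < alpha).fillna(False)
    return DEResult(
        table=table,
        contrast=contrast,
        alpha=alpha,
        meta={"n_samples": len(meta), "covariates": covariates},
    )


# ---------------------------------------------------------------------------
# Outlier controls
# ---------------------------------------------------------------------------


def flag_outlier_controls(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    marker_gene: str,
    k: float = 3.0,
    factors: pd.Series | None = None,
) -> list[str]:
    """Flag control libraries with anomalous marker expression.

    For each cell type, peers are all ``genotype == control`` libraries of
    that cell type across stages; a library is flagged when its
    size-factor-normalized marker expression — on the log2(x + 1) scale,
    where multiplicative suppression is additive and NB noise is roughly
    homoscedastic — deviates from the peer median by more than ``k`` scaled
    median absolute deviations (1.4826 * MAD). Strata with fewer than 3
    control peers are skipped with a warning.
    """
    if marker_gene not in counts.gene_ids:
        raise ValueError(f"marker gene {marker_gene!r} not in count matrix")
    if factors is None:
        factors = size_factors(counts)
    meta = metadata.loc[counts.sample_ids]
    norm = np.log2(counts.data.loc[marker_gene] / factors.reindex(counts.sample_ids) + 1.0)
    flagged: list[str] = []
    for cell_type, sub in meta[meta["genotype"] == "control"].groupby("cell_type", observed=True):
        x = norm.loc[sub.index].to_numpy(float)
        if len(x) < 3:
            logger.warning(
                "cell type %s has only %d control samples; outlier flagging skipped",
                cell_type, len(x),
            )
            continue
        med = np.median(x)
        mad = 1.4826 * np.median(np.abs(x - med))
        dev = np.abs(x - med)
        with np.errstate(invalid="ignore"):
            mask = dev > k * mad  # k=inf with mad=0 gives NaN: never flags
        flagged.extend(sub.index[mask])
    return sorted(flagged)
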