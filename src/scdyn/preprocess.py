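"""Cell QC, log2(CPM+1) normalisation and highly-variable-gene detection.

QC keeps a cell only if it passes all five thresholds (endogenous counts,
genes detected, top-100 count concentration, mitochondrial fraction,
mapping rate). Normalisation defaults to library-size (CPM) size factors;
a hook accepts user-supplied size factors on the same scale. Highly
variable genes are called from per-gene variances of experiment-corrected
residuals against a monotone mean-variance trend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from scdyn.config import QcThresholds


def qc_metrics(
    counts: np.ndarray, is_mt: np.ndarray
) -> pd.DataFrame:
    """Per-cell QC metrics from a cells x genes count matrix."""
    counts = np.asarray(counts)
    endo = counts[:, ~is_mt].sum(axis=1)
    total = counts.sum(axis=1)
    genes_detected = (counts > 0).sum(axis=1)
    top100 = np.sort(counts, axis=1)[:, -100:].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        top100_frac = np.where(total > 0, top100 / total, 0.0)
        mt_frac = np.where(total > 0, counts[:, is_mt].sum(axis=1) / total, 0.0)
    return pd.DataFrame(
        {
            "endogenous_counts": endo,
            "genes_detected": genes_detected,
            "top100_fraction": top100_frac,
            "mt_fraction": mt_frac,
        }
    )


def qc_filter_cells(
    adata,
    thresholds: QcThresholds | None = None,
) -> pd.Index:
    """Return ids of cells passing all QC thresholds, in input order.

    Requires ``adata.var["is_mt"]`` and ``adata.obs["mapping_rate"]``;
    raises a ``ValueError`` naming the first offending cell if the
    mapping rate is missing.
    """
    thresholds = thresholds or QcThresholds()
    if "is_mt" not in adata.var.columns:
        raise ValueError("gene metadata must provide an 'is_mt' column")
    if "mapping_rate" not in adata.obs.columns:
        raise ValueError("cell metadata must provide a 'mapping_rate' column")
    rate = adata.obs["mapping_rate"]
    if rate.isna().any():
        bad = adata.obs_names[rate.isna()][0]
        raise ValueError(f"cell {bad!r} lacks a mapping rate")

    m = qc_metrics(np.asarray(adata.X), adata.var["is_mt"].to_numpy(bool))
    m.index = adata.obs_names
    keep = (
        (m["endogenous_counts"] >= thresholds.min_endogenous_counts)
        & (m["genes_detected"] >= thresholds.min_genes_detected)
        # a threshold of 1.0 disables the criterion (fractions never exceed 1)
        & (
            (m["top100_fraction"] < thresholds.max_top100_fraction)
            | (thresholds.max_top100_fraction >= 1.0)
        )
        & (m["mt_fraction"] < thresholds.max_mt_fraction)
        & (rate >= thresholds.min_mapping_rate)
    )
    return adata.obs_names[keep.to_numpy()]


def normalize_log_cpm(
    counts: np.ndarray, size_factors: np.ndarray | None = None
) -> np.ndarray:
    """log2(CPM+1) for a cells x genes count matrix.

    Size factors default to library size scaled to counts-per-million;
    user-supplied factors replace the library size on the same scale
    (normalised value = 1e6 * count / size_factor).
    """
    counts = np.asarray(counts, dtype=float)
    if size_factors is None:
        size_factors = counts.sum(axis=1)
    size_factors = np.asarray(size_factors, dtype=float)
    if (size_factors <= 0).any():
        bad = int(np.flatnonzero(size_factors <= 0)[0])
        raise ValueError(
            f"cell at position {bad} has non-positive size factor "
            "(all-zero cells should have been removed by QC)"
        )
    cpm = 1e6 * counts / size_factors[:, None]
    return np.log2(cpm + 1.0)


def filter_expressed_genes(
    counts_pre_qc: pd.DataFrame,
    batches_pre_qc: pd.Series,
    logcpm_post_qc: pd.DataFrame,
    batches_post_qc: pd.Series,
    min_raw_count: int = 100,
    min_mean_log: float = 1.0,
) -> pd.Index:
    """Expressed-gene filter applied per batch with union semantics.

    Within each batch, a gene passes if (i) its raw count exceeds
    ``min_raw_count`` in at least one pre-QC cell of that batch and
    (ii) its mean log2(CPM+1) over that batch's post-QC cells exceeds
    ``min_mean_log``. A gene is kept if it passes in any batch.

    Both expression frames are cells x genes and must share the gene
    universe.
    """
    if not counts_pre_qc.columns.equals(logcpm_post_qc.columns):
        raise ValueError("pre-QC and post-QC matrices must share genes")
    kept = pd.Series(False, index=counts_pre_qc.columns)
    for batch in pd.unique(batches_pre_qc):
        pre = counts_pre_qc.loc[batches_pre_qc.to_numpy() == batch]
        post = logcpm_post_qc.loc[batches_post_qc.to_numpy() == batch]
        if len(post) == 0:
            continue
        crit1 = (pre > min_raw_count).any(axis=0)
        crit2 = post.mean(axis=0) > min_mean_log
        kept |= crit1 & crit2
    return kept.index[kept]


def highly_variable_genes(
    logcpm: pd.DataFrame,
    experiments: pd.Series | None = None,
    fdr: float = 0.01,
    span: float = 0.3,
) -> pd.DataFrame:
    """Detect highly variable genes against a monotone mean-variance trend.

    Per gene, the variance is computed on residuals after removing
    experiment-specific means (a design-matrix correction treating each
    differentiation experiment as a batch). A lowess trend of variance
    on mean expression (span 0.3), made monotone non-decreasing by
    isotonic regression, estimates the technical component; biological
    variance is total minus trend. Significance of variance excess uses
    a scaled chi-square for the residual degrees of freedom, with BH
    correction at ``fdr``.

    Returns a gene-indexed frame with columns mean, var_total, var_trend,
    var_biological, p_value, fdr_pass, sorted by decreasing biological
    variance.
    """
    x = np.asarray(logcpm, dtype=float)
    n_cells, n_genes = x.shape
    if n_genes < 10:
        raise ValueError("need at least 10 genes to fit a mean-variance trend")

    if experiments is not None and pd.Series(experiments).nunique() > 1:
        resid = np.empty_like(x)
        groups = pd.Series(np.asarray(experiments), index=logcpm.index)
        n_levels = groups.nunique()
        for _, idx in groups.groupby(groups).groups.items():
            pos = logcpm.index.get_indexer(idx)
            resid[pos] = x[pos] - x[pos].mean(axis=0, keepdims=True)
        df_resid = n_cells - n_levels
    else:
        resid = x - x.mean(axis=0, keepdims=True)
        df_resid = n_cells - 1

    mean = x.mean(axis=0)
    var_total = (resid**2).sum(axis=0) / df_resid

    order = np.argsort(mean, kind="stable")
    smoothed = lowess(
        var_total[order], mean[order], frac=span, return_sorted=False
    )
    iso = IsotonicRegression(y_min=0.0, increasing=True)
    trend_sorted = iso.fit_transform(mean[order], smoothed)
    trend = np.empty(n_genes)
    trend[order] = trend_sorted
    trend = np.maximum(trend, 1e-12)

    ratio = var_total / trend
    p = stats.chi2.sf(df_resid * ratio, df_resid)
    flag = multipletests(p, alpha=fdr, method="fdr_bh")[0]

    out = pd.DataFrame(
        {
            "mean": mean,
            "var_total": var_total,
            "var_trend": trend,
            "var_biological": var_total - trend,
            "p_value": p,
            "fdr_pass": flag,
        },
        index=logcpm.columns,
    )
    return out.sort_values("var_biological", ascending=False)
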