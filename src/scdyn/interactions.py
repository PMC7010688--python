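"""ASE regression tests for dynamic, cellular-factor and higher-order effects.

Three nested linear models on per-cell allelic fractions, compared by
Gaussian likelihood-ratio tests:

- dynamic: ``ASE ~ 1 + pseudo + pseudo^2`` against ``ASE ~ 1``
  (2 degrees of freedom) — does the allelic effect change along the
  differentiation trajectory?
- factor (GxE): adds a cellular-factor term to the dynamic model
  (1 df, pseudotime covariates always included) — does a cell-state
  factor modulate the allelic effect beyond the trajectory?
- higher-order (GxExE): adds ``pseudo x factor`` to the factor model
  (1 df) — does the factor effect itself change along pseudotime?

Fractions enter unweighted; eQTL with fewer than ``min_cells`` records
are skipped. Each family is BH-corrected separately; families are never
pooled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import SpectralClustering
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = [
    "gene", "variant", "family", "factor", "n", "stat", "df", "p",
    "coef", "slope", "resid_var", "skipped",
]


def _gaussian_lrt(y: np.ndarray, X_null: np.ndarray, X_full: np.ndarray):
    """LRT of nested OLS mean models with profiled residual variance."""
    n = len(y)
    b0, *_ = np.linalg.lstsq(X_null, y, rcond=None)
    r0 = y - X_null @ b0
    b1, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    r1 = y - X_full @ b1
    rss0 = float(r0 @ r0)
    rss1 = max(float(r1 @ r1), 1e-300)
    stat = max(n * (np.log(rss0) - np.log(rss1)), 0.0)
    df = X_full.shape[1] - X_null.shape[1]
    return stat, df, float(stats.chi2.sf(stat, df)), b1, rss1 / n


def _per_eqtl(
    records: pd.DataFrame,
    pt: pd.Series,
    factor: pd.Series | None,
    family: str,
    factor_name: str,
    min_cells: int,
) -> pd.DataFrame:
    rows = []
    for (gene, variant), sub in records.groupby(["gene", "variant"], observed=True):
        y = sub["fraction"].to_numpy(dtype=float)
        cells = sub["cell"]
        t = pt.loc[cells].to_numpy(dtype=float)
        n = len(y)
        if n < min_cells:
            rows.append(
                (gene, variant, family, factor_name, n, np.nan, np.nan,
                 np.nan, np.nan, np.nan, np.nan, True)
            )
            continue
        ones = np.ones(n)
        base = np.column_stack([ones, t, t * t])
        if family == "dynamic":
            X_null, X_full = ones[:, None], base
        else:
            f = factor.loc[cells].to_numpy(dtype=float)
            if np.std(f) == 0:
                rows.append(
                    (gene, variant, family, factor_name, n, np.nan, np.nan,
                     np.nan, np.nan, np.nan, np.nan, True)
                )
                continue
            if family == "factor":
                X_null = base
                X_full = np.column_stack([base, f])
            elif family == "higher_order":
                X_null = np.column_stack([base, f])
                X_full = np.column_stack([base, f, t * f])
            else:
                raise ValueError(f"unknown test family {family!r}")
        stat, df, p, coefs, rvar = _gaussian_lrt(y, X_null, X_full)
        # coef: the tested (last) term; slope: the marginal allelic
        # trend d(ASE)/d(pseudotime) averaged over the observed cells,
        # b1 + 2 * b2 * mean(pt) (the raw linear coefficient alone is
        # confounded by the collinear quadratic term)
        coef = float(coefs[-1])
        slope = (
            float(coefs[1] + 2.0 * coefs[2] * t.mean())
            if family == "dynamic"
            else np.nan
        )
        rows.append(
            (gene, variant, family, factor_name, n, stat, df, p, coef,
             slope, rvar, False)
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def test_dynamic(
    records: pd.DataFrame, pt: pd.Series, min_cells: int = 50
) -> pd.DataFrame:
    """Joint linear + quadratic pseudotime dependence of ASE (2-df LRT)."""
    return _per_eqtl(records, pt, None, "dynamic", "", min_cells)


def test_factor(
    records: pd.DataFrame,
    pt: pd.Series,
    factor: pd.Series,
    factor_name: str = "factor",
    min_cells: int = 50,
) -> pd.DataFrame:
    """Cellular-factor (GxE) effect on ASE, pseudotime-corrected (1-df LRT)."""
    return _per_eqtl(records, pt, factor, "factor", factor_name, min_cells)


def test_higher_order(
    records: pd.DataFrame,
    pt: pd.Series,
    factor: pd.Series,
    factor_name: str = "factor",
    min_cells: int = 50,
) -> pd.DataFrame:
    """Pseudotime x factor interaction (GxExE) effect on ASE (1-df LRT)."""
    return _per_eqtl(records, pt, factor, "higher_order", factor_name, min_cells)


def bh_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment within one homogeneous test family."""
    families = results.loc[~results["skipped"], "family"].unique()
    if len(families) > 1:
        raise ValueError("families must be adjusted separately, never pooled")
    out = results.copy()
    out["p_bh"] = np.nan
    tested = ~out["skipped"] & out["p"].notna()
    if tested.any():
        out.loc[tested, "p_bh"] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def classify_eqtl(
    dynamic: pd.DataFrame,
    factor_families: list[pd.DataFrame],
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Per-eQTL category: pseudotime-only, factor-only, both or none.

    Pseudotime significance comes from the BH-adjusted dynamic family;
    factor significance means any cellular factor significant in its
    (BH-adjusted) GxE family.
    """
    dyn = dynamic.set_index(["gene", "variant"])
    dyn_sig = dyn["p_bh"] < fdr

    fac_sig = pd.Series(False, index=dyn.index)
    for fam in factor_families:
        f = fam.set_index(["gene", "variant"])
        sig = (f["p_bh"] < fdr).reindex(fac_sig.index, fill_value=False)
        fac_sig |= sig

    def label(d: bool, f: bool) -> str:
        if d and f:
            return "both"
        if d:
            return "pseudotime-only"
        if f:
            return "factor-only"
        return "none"

    cats = [
        label(bool(dyn_sig.loc[i]), bool(fac_sig.loc[i])) for i in dyn.index
    ]
    out = dyn.reset_index()[["gene", "variant"]]
    out["category"] = cats
    return out


def cluster_dynamics(
    expression_profiles: pd.DataFrame,
    ase_profiles: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Jointly cluster window profiles of expression and ASE.

    Profiles (rows = eQTL, columns = windows) are z-scored per row,
    stacked, and clustered spectrally with affinity ``(1 + r) / 2``
    derived from the Pearson correlation between profiles (the negative
    correlation acting as dissimilarity). Returns the expression
    labels, the ASE labels and the cluster mean profiles.
    """
    n_profiles = len(expression_profiles) + len(ase_profiles)
    if k > n_profiles:
        raise ValueError("more clusters requested than profiles")

    def zrow(df: pd.DataFrame) -> pd.DataFrame:
        x = df.to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return pd.DataFrame((x - mu) / sd, index=df.index, columns=df.columns)

    stacked = pd.concat([zrow(expression_profiles), zrow(ase_profiles)])
    r = np.corrcoef(stacked.to_numpy())
    affinity = (1.0 + r) / 2.0
    model = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed,
        assign_labels="kmeans",
    )
    labels = model.fit_predict(affinity)
    n_expr = len(expression_profiles)
    expr_labels = pd.Series(
        labels[:n_expr], index=expression_profiles.index, name="cluster"
    )
    ase_labels = pd.Series(
        labels[n_expr:], index=ase_profiles.index, name="cluster"
    )
    means = stacked.groupby(labels).mean()
    means.index.name = "cluster"
    return expr_labels, ase_labels, means
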