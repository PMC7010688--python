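"""Pseudo-bulk cis-eQTL mapping with a kinship linear mixed model.

Expression is aggregated to (donor, day-or-stage, experiment) means of
log2(CPM+1); repeated donors across experiments are genetically
identical, which the kinship random effect absorbs. Per gene, common
variants (sample MAF above threshold) within a cis window around the
gene body are tested by a likelihood-ratio test in the mixed model
``y = covariates c + x b + u + e`` with ``u ~ N(0, sg^2 K)``; the
variance ratio is fitted once per gene under the null and reused across
variants. Gene-level multiple testing uses genotype permutations (donor
relabelling) and the Storey q-value procedure across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from scdyn.datatypes import PhasedGenotypes
from scdyn.lmm import KinshipEigen, fit_null_lmm, lrt_variants

RESULT_COLUMNS = [
    "gene", "variant", "chrom", "pos", "beta", "se", "stat", "p",
    "p_adjusted", "q_value", "lead", "n_samples", "maf",
]


@dataclass
class AggregatedExpression:
    """Pseudo-bulk expression: group means of log2(CPM+1).

    ``expr`` is samples x genes; ``samples`` carries donor, the stratum
    column (day or stage), experiment and the contributing cell count.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame
    stratum: str


def aggregate_expression(
    logcpm: pd.DataFrame, meta: pd.DataFrame, group_by: str = "day"
) -> AggregatedExpression:
    """Average expression over (donor, ``group_by``, experiment) groups.

    Unweighted means across member cells; empty groups are absent. A
    donor differentiated in two experiments contributes one row per
    experiment, preserving between-experiment differences.
    """
    if group_by not in meta.columns:
        raise ValueError(f"metadata lacks column {group_by!r}")
    keys = ["donor", group_by, "experiment"]
    df = logcpm.copy()
    grouped = df.groupby(
        [meta[k].loc[df.index].astype(str) for k in keys], observed=True
    )
    expr = grouped.mean()
    counts = grouped.size()
    samples = expr.index.to_frame(index=False)
    samples.columns = keys
    samples["n_cells"] = counts.to_numpy()
    sample_ids = pd.Index(
        ["::".join(map(str, tup)) for tup in expr.index], name="sample"
    )
    expr.index = sample_ids
    samples.index = sample_ids
    return AggregatedExpression(expr=expr, samples=samples, stratum=group_by)


@dataclass
class Kinship:
    """Donor x donor realised genetic relatedness ``Z Z^T / m``."""

    K: pd.DataFrame
    n_variants: int

    def expand(self, donors: pd.Series) -> np.ndarray:
        """Replicate rows/columns per analysis sample."""
        idx = self.K.index.get_indexer(donors)
        if (idx < 0).any():
            missing = sorted(set(donors) - set(self.K.index))
            raise KeyError(f"donors missing from kinship: {missing}")
        return self.K.to_numpy()[np.ix_(idx, idx)]


def estimate_kinship(genotypes: PhasedGenotypes) -> Kinship:
    """Realised kinship from standardised dosages (monomorphic skipped)."""
    if genotypes.n_donors < 2:
        raise ValueError("kinship needs at least 2 donors")
    G = genotypes.dosages().to_numpy(dtype=float)
    sd = G.std(axis=0, ddof=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("no polymorphic variants")
    Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
    m = int(poly.sum())
    K = Z @ Z.T / m
    return Kinship(
        K=pd.DataFrame(K, index=genotypes.donors, columns=genotypes.donors),
        n_variants=m,
    )


def variance_components(
    logcpm: pd.DataFrame,
    meta: pd.DataFrame,
    genes: list[str] | None = None,
    max_cells: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene variance fractions for experiment, day, line and residual.

    Fits a random-effects model (REML) to each gene's expression across
    a random subset of cells; fractions are variance components divided
    by their sum. Non-converged genes carry NaN fractions.
    """
    from scdyn.lmm import fit_crossed_lmm

    genes = list(genes) if genes is not None else list(logcpm.columns)
    rng = np.random.default_rng(seed)
    if len(logcpm) > max_cells:
        cells = rng.choice(logcpm.index, max_cells, replace=False)
    else:
        cells = logcpm.index
    sub = logcpm.loc[cells]
    re = {
        "experiment": meta.loc[cells, "experiment"].to_numpy(),
        "day": meta.loc[cells, "day"].to_numpy(),
        "line": meta.loc[cells, "donor"].to_numpy(),
    }
    for name, labels in re.items():
        if len(np.unique(labels)) < 2:
            raise ValueError(f"random effect {name!r} needs >= 2 levels")
    X = np.ones((len(cells), 1))

    rows = []
    for gene in genes:
        y = sub[gene].to_numpy(dtype=float)
        if y.std() == 0:
            rows.append((gene, *([np.nan] * 4), False))
            continue
        fit = fit_crossed_lmm(y, X, re, reml=True)
        total = sum(fit.variances.values())
        fr = {k: v / total for k, v in fit.variances.items()}
        rows.append(
            (gene, fr["experiment"], fr["day"], fr["line"], fr["residual"],
             fit.converged)
        )
    return pd.DataFrame(
        rows, columns=["gene", "experiment", "day", "line", "residual", "converged"]
    ).set_index("gene")


def expression_pcs(expr: pd.DataFrame, n_pcs: int = 10) -> np.ndarray:
    """Principal components of the aggregated matrix, genes standardised."""
    x = expr.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=0)
    x = x[:, sd > 0] / sd[sd > 0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, (s > 1e-10).sum())
    return u[:, :k] * s[:k]


def _cis_variants(
    genotypes: PhasedGenotypes,
    chrom: str,
    start: int,
    end: int,
    window: int,
    donors: np.ndarray,
    maf_min: float,
) -> pd.Index:
    v = genotypes.variants
    in_cis = (
        (v["chrom"].astype(str) == str(chrom))
        & (v["pos"] >= start - window)
        & (v["pos"] <= end + window)
    )
    sub = v.loc[in_cis]
    # canonical genomic order (position, then id), independent of the
    # order variants happen to be stored in
    order = np.lexsort((sub.index.to_numpy(), sub["pos"].to_numpy()))
    ids = sub.index[order]
    if len(ids) == 0:
        return ids
    dos = genotypes.dosages().loc[donors, ids]
    freq = dos.to_numpy().mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    return ids[maf > maf_min]


def empirical_adjusted_p(obs_min_p: float, perm_min_p: np.ndarray) -> float:
    """Empirical tail probability with a +1 pseudocount."""
    n_perm = len(perm_min_p)
    return (1 + int((perm_min_p <= obs_min_p).sum())) / (n_perm + 1)


def map_cis_eqtl(
    agg: AggregatedExpression,
    genotypes: PhasedGenotypes,
    annot: pd.DataFrame,
    kinship: Kinship,
    n_expr_pcs: int = 10,
    window: int = 250_000,
    maf_min: float = 0.05,
    n_perm: int = 0,
    seed: int = 0,
    genes: list[str] | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Map cis eQTL for one stratum of aggregated expression.

    Phenotypes and genotype dosages are standardised, so ``beta`` is in
    phenotype standard deviations per standardised allele. The lead
    variant per gene is the smallest p, ties broken by distance to the
    gene start then by genomic position. With ``n_perm > 0``, donor
    labels of the genotypes are permuted while expression, covariates
    and kinship stay fixed; the gene-level adjusted p is the empirical
    tail of the permuted minimum p with a +1 pseudocount. Gene-level
    q-values (Storey) are attached to lead rows when permutations ran.
    ``covariates`` adds user design columns (samples x k, e.g. batch
    indicators) alongside the intercept and expression PCs.
    """
    donors_per_sample = agg.samples["donor"]
    unique_donors = pd.unique(donors_per_sample)
    K = kinship.expand(donors_per_sample)
    eigen = KinshipEigen.from_kinship(K)
    pcs = expression_pcs(agg.expr, n_expr_pcs)
    extra = (
        [np.atleast_2d(np.asarray(covariates, dtype=float))]
        if covariates is not None
        else []
    )
    W = np.column_stack([np.ones(len(agg.expr)), pcs, *extra])
    rng = np.random.default_rng(seed)

    dosage_donor = genotypes.dosages().loc[unique_donors]
    donor_pos = pd.Index(unique_donors).get_indexer(donors_per_sample)

    gene_list = genes if genes is not None else [
        g for g in agg.expr.columns if g in annot.index
    ]

    records: list[pd.DataFrame] = []
    skipped: list[str] = []
    for gene in gene_list:
        row = annot.loc[gene]
        cis = _cis_variants(
            genotypes, row["chrom"], int(row["start"]), int(row["end"]),
            window, unique_donors, maf_min,
        )
        if len(cis) == 0:
            skipped.append(gene)
            continue
        y = agg.expr[gene].to_numpy(dtype=float)
        sd = y.std(ddof=0)
        if sd == 0:
            skipped.append(gene)
            continue
        y = (y - y.mean()) / sd

        dos_d = dosage_donor[cis].to_numpy(dtype=float)
        mu, s = dos_d.mean(axis=0), dos_d.std(axis=0, ddof=0)
        dos_std = (dos_d - mu) / np.where(s > 0, s, 1.0)
        X = dos_std[donor_pos]

        null = fit_null_lmm(y, W, eigen)
        res = lrt_variants(null, X)

        out = pd.DataFrame(
            {
                "gene": gene,
                "variant": cis,
                "chrom": genotypes.variants.loc[cis, "chrom"].to_numpy(),
                "pos": genotypes.variants.loc[cis, "pos"].to_numpy(),
                "beta": res["beta"],
                "se": res["se"],
                "stat": res["stat"],
                "p": res["p"],
                "n_samples": len(y),
                "maf": np.minimum(mu / 2.0, 1 - mu / 2.0),
            }
        )
        dist = np.abs(out["pos"].to_numpy() - int(row["start"]))
        order = np.lexsort((out["pos"].to_numpy(), dist, out["p"].to_numpy()))
        out["lead"] = False
        out.iloc[order[0], out.columns.get_loc("lead")] = True

        if n_perm > 0:
            obs_max_stat = float(np.nanmax(out["stat"]))
            perm_max = _permute_max_stats(
                null, dos_std, donor_pos, n_perm, rng
            )
            obs_min_p = stats.chi2.sf(obs_max_stat, 1)
            perm_min_p = stats.chi2.sf(perm_max, 1)
            out["p_adjusted"] = np.nan
            out.loc[out["lead"], "p_adjusted"] = empirical_adjusted_p(
                obs_min_p, perm_min_p
            )
        else:
            out["p_adjusted"] = np.nan
        records.append(out)

    if not records:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    result = pd.concat(records, ignore_index=True)
    result["q_value"] = np.nan
    if n_perm > 0:
        leads = result["lead"]
        q, _ = storey_fdr(result.loc[leads, "p_adjusted"].to_numpy())
        result.loc[leads, "q_value"] = q
    return result[RESULT_COLUMNS]


def _permute_max_stats(
    null, dos_std: np.ndarray, donor_pos: np.ndarray, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max LRT statistic across a gene's cis variants per donor permutation."""
    n_donors, n_var = dos_std.shape
    perms = np.stack([rng.permutation(n_donors) for _ in range(n_perm)])
    # (samples, n_perm * n_var): donor labels permuted, then expanded
    Xp = dos_std[perms[:, donor_pos], :]  # (n_perm, samples, n_var)
    Xp = np.moveaxis(Xp, 0, 1).reshape(len(donor_pos), n_perm * n_var)
    res = lrt_variants(null, Xp)
    stat = res["stat"].reshape(n_perm, n_var)
    return np.nanmax(stat, axis=1)


def storey_fdr(
    p: np.ndarray,
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoothed pi0 estimation.

    pi0 is estimated on a lambda grid (0.05 ... 0.95 by 0.05) via a
    cubic smoothing of ``mean(p > lambda) / (1 - lambda)`` evaluated at
    the largest lambda, clipped to (0, 1]. Forcing ``pi0 = 1`` recovers
    Benjamini-Hochberg exactly. Returns (q, pi0) with q in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)

    if pi0 is None:
        pi0_l = np.array([(p > l).mean() / (1.0 - l) for l in lambdas])
        if np.all(pi0_l == 0):
            pi0 = 1.0 / len(p)
        else:
            spl = interpolate.UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spl(lambdas[-1]))
        pi0 = min(max(pi0, 1.0 / len(p)), 1.0)

    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * n * ranked / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def replicate_and_share(
    lead_a: pd.DataFrame, full_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Sharing of stratum-A lead eQTL in stratum B.

    A lead effect is ``shared`` when the same variant reaches nominal
    significance in B with a consistent direction; ``specific``
    otherwise; ``untestable`` when B never tested the variant.
    """
    b_idx = full_b.set_index(["gene", "variant"])
    rows = []
    for _, r in lead_a.iterrows():
        key = (r["gene"], r["variant"])
        if key not in b_idx.index:
            status, p_b, beta_b = "untestable", np.nan, np.nan
        else:
            hit = b_idx.loc[key]
            p_b, beta_b = float(hit["p"]), float(hit["beta"])
            same_dir = np.sign(beta_b) == np.sign(r["beta"])
            status = "shared" if (p_b < alpha and same_dir) else "specific"
        rows.append((r["gene"], r["variant"], r["beta"], p_b, beta_b, status))
    return pd.DataFrame(
        rows, columns=["gene", "variant", "beta_a", "p_b", "beta_b", "status"]
    )


def ld_r2(genotypes: PhasedGenotypes, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of dosages."""
    a = genotypes.dosage(variant_a).to_numpy(dtype=float)
    b = genotypes.dosage(variant_b).to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for monomorphic variants")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def detect_lead_switches(
    results_by_stratum: dict[str, pd.DataFrame],
    genotypes: PhasedGenotypes,
    r2_max: float = 0.2,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Genes whose lead variants differ between strata and are not in LD.

    An event requires distinct lead variants in distinct strata, each
    significant (q-value below ``fdr``), with all pairwise r-squared
    below ``r2_max``.
    """
    if len(results_by_stratum) < 2:
        raise ValueError("need at least two strata")
    leads: dict[str, pd.DataFrame] = {}
    for stratum, res in results_by_stratum.items():
        sig = res[(res["lead"]) & (res["q_value"] < fdr)]
        leads[stratum] = sig.set_index("gene")

    genes = sorted(set().union(*[set(df.index) for df in leads.values()]))
    events = []
    for gene in genes:
        found = {
            s: df.loc[gene, "variant"] for s, df in leads.items() if gene in df.index
        }
        variants = sorted(set(found.values()))
        if len(variants) < 2:
            continue
        pairs_ok = all(
            ld_r2(genotypes, a, b) < r2_max
            for i, a in enumerate(variants)
            for b in variants[i + 1:]
        )
        if pairs_ok:
            events.append(
                (gene, ";".join(f"{s}:{v}" for s, v in sorted(found.items())))
            )
    return pd.DataFrame(events, columns=["gene", "leads"])
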