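"""Differentiation efficiency and marker association.

Differentiation efficiency of a (donor, experiment) pair is the mean
pseudotime of its day-3 cells; pairs with too few cells are excluded.
Candidate markers — eQTL allele dosages, iPSC-stage expression levels,
or donor sex — are tested in a linear mixed model with random
intercepts for experiment and donor:

    efficiency = marker + (1 | experiment) + (1 | donor) + noise

with ML likelihood-ratio tests and BH correction across markers.
Replication in independent measurements uses simple linear regression
(nominal p < 0.05 with a consistent direction). A Fisher exact test
quantifies chromosome enrichment of significant expression markers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from scdyn.lmm import lrt_fixed_effect

MARKER_COLUMNS = [
    "marker", "kind", "effect", "stat", "p", "p_bh", "n", "converged",
]


def differentiation_efficiency(
    pt: pd.Series,
    meta: pd.DataFrame,
    min_cells: int = 10,
    day: str = "day3",
) -> pd.DataFrame:
    """Mean day-3 pseudotime per (donor, experiment).

    Groups with fewer than ``min_cells`` contributing cells are
    excluded. Returns columns donor, experiment, efficiency, n_cells.
    """
    sel = meta["day"].astype(str) == day
    if not sel.any():
        raise ValueError(f"no cells collected at {day}")
    sub = meta.loc[sel, ["donor", "experiment"]].copy()
    sub["pt"] = pt.loc[sub.index]
    g = sub.groupby(["donor", "experiment"], observed=True)["pt"]
    out = g.agg(efficiency="mean", n_cells="size").reset_index()
    out = out[out["n_cells"] >= min_cells].reset_index(drop=True)
    if out.empty:
        raise ValueError("no (donor, experiment) group meets the cell minimum")
    return out


def _lmm_records(records: pd.DataFrame):
    if records["experiment"].nunique() < 2 or records["donor"].nunique() < 2:
        raise ValueError("need >= 2 experiments and >= 2 donors")
    return {
        "experiment": records["experiment"].to_numpy(),
        "donor": records["donor"].to_numpy(),
    }


def test_marker_lmm(
    records: pd.DataFrame,
    markers: pd.DataFrame,
    kind: str = "genetic",
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Mixed-model association of each marker with efficiency.

    ``markers`` is indexed by donor (one column per marker; e.g. eQTL
    lead-variant dosages 0/1/2, or iPSC expression per donor). The LRT
    compares the model with and without the fixed marker effect at
    1 df; BH adjusts across markers.
    """
    re = _lmm_records(records)
    y = records["efficiency"].to_numpy(dtype=float)
    n = len(records)
    ones = np.ones((n, 1))
    rows = []
    for name in markers.columns:
        x = markers[name].reindex(records["donor"]).to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"marker {name!r} missing for some donors")
        if np.std(x) == 0:
            rows.append((name, kind, 0.0, 0.0, 1.0, np.nan, n, True))
            continue
        res = lrt_fixed_effect(
            y, np.column_stack([ones, x]), ones, re, df=1
        )
        rows.append(
            (name, kind, res["beta"], res["stat"], res["p"], np.nan, n,
             bool(res["converged"]))
        )
    out = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p_bh"] < fdr
    return out


def replicate_marker(
    response: pd.Series, marker: pd.Series, discovery_direction: float
) -> dict:
    """Replication by simple linear regression on overlapping donors.

    Replicated means nominal p < 0.05 with the same effect direction as
    the discovery estimate.
    """
    common = response.index.intersection(marker.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping donors for replication")
    res = stats.linregress(
        marker.loc[common].to_numpy(dtype=float),
        response.loc[common].to_numpy(dtype=float),
    )
    same_dir = np.sign(res.slope) == np.sign(discovery_direction)
    return {
        "slope": float(res.slope),
        "p": float(res.pvalue),
        "n": int(len(common)),
        "consistent_direction": bool(same_dir),
        "replicated": bool(res.pvalue < 0.05 and same_dir),
    }


def test_sex_effect(records: pd.DataFrame, donor_sex: pd.Series) -> dict:
    """Mixed-model LRT of donor sex on differentiation efficiency."""
    sexes = donor_sex.reindex(pd.unique(records["donor"]))
    if sexes.isna().any():
        raise ValueError("sex missing for some donors")
    if sexes.nunique() < 2:
        raise ValueError("both sexes must be present")
    re = _lmm_records(records)
    y = records["efficiency"].to_numpy(dtype=float)
    # deterministic coding: second sorted category is 1, so relabelling
    # the sexes flips the sign of the estimated effect
    cats = sorted(sexes.unique())
    codes = (
        donor_sex.reindex(records["donor"]).to_numpy() == cats[1]
    ).astype(float)
    n = len(records)
    ones = np.ones((n, 1))
    res = lrt_fixed_effect(
        y, np.column_stack([ones, codes.astype(float)]), ones, re, df=1
    )
    return {"effect": res["beta"], "stat": res["stat"], "p": res["p"]}


def chromosome_enrichment(
    significant_genes,
    gene_chrom: pd.Series,
    universe,
    chrom: str = "X",
) -> dict:
    """Fold enrichment and Fisher p of a chromosome among significant markers.

    Fold enrichment is ``(hits_on_chrom / hits) / (universe_on_chrom /
    universe)``; the p-value comes from the one-sided Fisher exact test
    of the 2x2 membership table.
    """
    hits = pd.Index(significant_genes)
    universe = pd.Index(universe)
    if len(hits) == 0:
        raise ValueError("empty set of significant markers")
    on = gene_chrom.reindex(universe).astype(str) == str(chrom)
    hit_mask = universe.isin(hits)
    a = int((on & hit_mask).sum())
    b = int((~on & hit_mask).sum())
    c = int((on & ~hit_mask).sum())
    d = int((~on & ~hit_mask).sum())
    frac_hits = a / (a + b)
    frac_univ = (a + c) / len(universe)
    fold = np.inf if frac_univ == 0 else frac_hits / frac_univ
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {"fold": float(fold), "p": float(p), "hits_on_chrom": a, "hits": a + b}
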