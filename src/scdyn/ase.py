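"""Gene-level phased allele-specific expression relative to an eQTL variant.

Starting from per-cell per-SNP allelic read counts at heterozygous
exonic SNPs, the workflow is:

1. convert alternative-allele reads to chrB-allele reads using each
   donor's phase (``chrA|chrB``, 0 = reference, 1 = alternative);
2. aggregate chrB and total reads across the exonic SNPs of each gene;
3. re-orient gene-level counts to the chromosome carrying the
   alternative allele of the gene's eQTL variant, again via phase, so
   the allelic fraction is comparable across donors; donors homozygous
   at the eQTL variant are dropped;
4. summarise fractions in sliding pseudotime windows, and convert to
   per-allele expression by scaling with the mean CPM among
   heterozygous cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scdyn.datatypes import PhasedGenotypes
from scdyn.trajectory import WindowSet


def phase_to_haplotype_counts(
    counts: pd.DataFrame, genotypes: PhasedGenotypes
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert alternative-allele reads to chrB-allele reads per (cell, SNP).

    ``counts`` needs columns cell, donor, gene, snp, alt_reads,
    total_reads. Records at SNPs where the donor is homozygous or
    unphased, or with zero total reads, are rejected. Returns
    ``(accepted, rejected)``; ``accepted`` gains a ``chrb_reads``
    column, ``rejected`` a ``reason`` column.
    """
    required = {"cell", "donor", "snp", "alt_reads", "total_reads"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"allelic count table lacks columns: {sorted(missing)}")

    df = counts.copy()
    di = pd.Index(genotypes.donors).get_indexer(df["donor"])
    vj = genotypes.variant_ids.get_indexer(df["snp"])
    if (di < 0).any() or (vj < 0).any():
        raise KeyError("allelic counts reference unknown donors or SNPs")

    hapA = genotypes.haplotypes[di, vj, 0]
    hapB = genotypes.haplotypes[di, vj, 1]
    phased = genotypes.phased[di, vj]
    het = hapA != hapB

    reason = np.full(len(df), "", dtype=object)
    reason[df["total_reads"].to_numpy() <= 0] = "no_reads"
    reason[~phased] = "unphased"
    reason[~het] = "homozygous"
    ok = reason == ""

    accepted = df.loc[ok].copy()
    alt = accepted["alt_reads"].to_numpy()
    total = accepted["total_reads"].to_numpy()
    alt_on_chrb = hapB[ok] == 1
    accepted["chrb_reads"] = np.where(alt_on_chrb, alt, total - alt)
    rejected = df.loc[~ok].copy()
    rejected["reason"] = reason[~ok]
    return accepted, rejected


def aggregate_ase_to_gene(
    hap_counts: pd.DataFrame, snp_gene: pd.Series | None = None
) -> pd.DataFrame:
    """Sum chrB and total reads over a gene's exonic SNPs per cell.

    The SNP-to-gene map defaults to the ``gene`` column of the input;
    SNPs mapping to no gene are dropped. Returns one row per
    (cell, donor, gene) with chrb_reads and total_reads.
    """
    df = hap_counts.copy()
    if snp_gene is not None:
        df["gene"] = df["snp"].map(snp_gene)
    if "gene" not in df.columns:
        raise ValueError("need a 'gene' column or an explicit SNP-to-gene map")
    df = df.dropna(subset=["gene"])
    out = (
        df.groupby(["cell", "donor", "gene"], observed=True)[
            ["chrb_reads", "total_reads"]
        ]
        .sum()
        .reset_index()
    )
    return out


def orient_to_eqtl_alt(
    gene_counts: pd.DataFrame,
    genotypes: PhasedGenotypes,
    eqtl_variants: pd.Series,
) -> pd.DataFrame:
    """Orient gene-level chrB reads to the eQTL alternative-allele chromosome.

    ``eqtl_variants`` maps gene -> eQTL variant id. For donors with
    eQTL phase ``0|1`` the alternative allele sits on chrB, so
    alt-chromosome reads equal chrB reads; for ``1|0`` they equal
    total minus chrB. Donors not heterozygous (or unphased) at the
    eQTL variant are dropped. Returns per (cell, gene, variant) rows
    with alt_chrom_reads, total_reads and the allelic fraction.
    """
    df = gene_counts[gene_counts["gene"].isin(eqtl_variants.index)].copy()
    if df.empty:
        return pd.DataFrame(
            columns=[
                "cell", "donor", "gene", "variant",
                "alt_chrom_reads", "total_reads", "fraction",
            ]
        )
    df["variant"] = df["gene"].map(eqtl_variants)
    di = pd.Index(genotypes.donors).get_indexer(df["donor"])
    vj = genotypes.variant_ids.get_indexer(df["variant"])
    if (vj < 0).any():
        bad = sorted(set(df["variant"][vj < 0]))
        raise KeyError(f"unknown eQTL variants: {bad}")

    hapA = genotypes.haplotypes[di, vj, 0]
    hapB = genotypes.haplotypes[di, vj, 1]
    het = (hapA != hapB) & genotypes.phased[di, vj]
    df = df.loc[het]
    alt_on_chrb = (hapB[het] == 1)
    chrb = df["chrb_reads"].to_numpy()
    total = df["total_reads"].to_numpy()
    df["alt_chrom_reads"] = np.where(alt_on_chrb, chrb, total - chrb)
    df["fraction"] = df["alt_chrom_reads"] / total
    return df[
        ["cell", "donor", "gene", "variant",
         "alt_chrom_reads", "total_reads", "fraction"]
    ].reset_index(drop=True)


def quantify_ase(
    counts: pd.DataFrame,
    genotypes: PhasedGenotypes,
    eqtl_variants: pd.Series,
) -> pd.DataFrame:
    """Full phase -> aggregate -> orient pipeline to AseGeneRecord rows."""
    hap, _ = phase_to_haplotype_counts(counts, genotypes)
    gene_level = aggregate_ase_to_gene(hap)
    return orient_to_eqtl_alt(gene_level, genotypes, eqtl_variants)


def bin_ase_pseudotime(
    records: pd.DataFrame, windows: WindowSet
) -> pd.DataFrame:
    """Mean / sd / SEM of allelic fractions per (eQTL gene, window).

    Windows hold equal numbers of cells but unequal numbers of ASE
    records; statistics use the member cells that carry a record for
    the gene. SEM is NaN for single-record windows.
    """
    rows = []
    for (gene, variant), sub in records.groupby(["gene", "variant"], observed=True):
        by_cell = sub.set_index("cell")["fraction"]
        for w in windows:
            vals = by_cell.reindex(w.cells).dropna().to_numpy()
            n = len(vals)
            if n == 0:
                mean = sd = sem = np.nan
            else:
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if n > 1 else np.nan
                sem = sd / np.sqrt(n) if n > 1 else np.nan
            rows.append((gene, variant, w.index, w.center, mean, sd, sem, n))
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "variant", "window", "center", "mean_ase", "sd", "sem", "n",
        ],
    )


def allelic_expression_dynamics(
    binned: pd.DataFrame,
    cpm: pd.DataFrame,
    records: pd.DataFrame,
    windows: WindowSet,
) -> pd.DataFrame:
    """Per-window expression of the two chromosomes, in CPM.

    The mean CPM of each gene per window is computed over the cells
    heterozygous for the eQTL variant (the cells with ASE records);
    the alt-chromosome expression is ``mean ASE x mean CPM`` and the
    other chromosome gets the complement, so the two alleles sum to
    the mean expression. SEM bands scale identically.
    """
    het_cells = records.groupby(["gene", "variant"], observed=True)["cell"].agg(set)
    out = []
    for (gene, variant), sub in binned.groupby(["gene", "variant"], observed=True):
        if gene not in cpm.columns:
            continue
        cells_with_rec = het_cells.loc[(gene, variant)]
        gene_cpm = cpm[gene]
        for _, r in sub.iterrows():
            w = windows.windows[int(r["window"])]
            members = [c for c in w.cells if c in cells_with_rec]
            if not members or not np.isfinite(r["mean_ase"]):
                continue
            mean_cpm = float(gene_cpm.loc[members].mean())
            alt = r["mean_ase"] * mean_cpm
            sem_scaled = (
                r["sem"] * mean_cpm if np.isfinite(r["sem"]) else np.nan
            )
            out.append(
                (
                    gene, variant, int(r["window"]), r["center"], mean_cpm,
                    alt, mean_cpm - alt, sem_scaled,
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "gene", "variant", "window", "center", "mean_cpm",
            "alt_chrom_cpm", "other_chrom_cpm", "sem_cpm",
        ],
    )
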