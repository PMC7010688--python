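"""Simulation of pooled multi-donor single-cell differentiation datasets.

The generator emulates the design of a pooled iPSC differentiation
experiment: several cell lines are differentiated together per experiment,
cells are collected on four days, a latent differentiation trajectory
(pseudotime) drives a block of genes, and donor identity, experimental
batch and residual noise contribute variance on the log2 scale. Genetic
effects are injected as cis-eQTL whose allelic effect may be constant
(static), change along pseudotime (dynamic), or — on the allelic-fraction
scale — depend on a latent cellular factor (GxE). Allelic read counts at
exonic heterozygous SNPs follow a beta-binomial on phased haplotypes.

All randomness flows from ``SimulationConfig.seed`` through separate
:class:`numpy.random.SeedSequence` children per stage, so each stage is
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit

from scdyn.config import SimulationConfig
from scdyn.datatypes import PhasedGenotypes

LN2 = np.log(2.0)

GENE_SPACING = 1_000_000
GENE_LENGTH = 10_000
CIS_WINDOW = 250_000
N_MT_GENES = 5
LOW_QUALITY_FRACTION = 0.02


@dataclass
class GroundTruth:
    """Latent quantities of one simulation run.

    ``genes`` holds per-gene injected effects (eQTL variant, static and
    dynamic allelic effect sizes on the log2 scale, GxE factor id and
    logit-scale effect, module membership, baseline, trajectory
    coefficient); ``cells`` holds per-cell latent pseudotime and factor
    values alongside the design columns.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame
    config: SimulationConfig

    def __post_init__(self) -> None:
        pt = self.cells["pseudotime"].to_numpy()
        if pt.min() < 0 or pt.max() > 1:
            raise ValueError("latent pseudotime must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """Bundle of all artefacts of one simulation run."""

    config: SimulationConfig
    genotypes: PhasedGenotypes
    adata: ad.AnnData
    truth: GroundTruth
    allelic_counts: pd.DataFrame


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _donor_ids(config: SimulationConfig) -> list[str]:
    return [f"donor{i:03d}" for i in range(config.n_donors)]


def _gene_ids(config: SimulationConfig) -> list[str]:
    return [f"gene{i:04d}" for i in range(config.n_genes)]


def _pool_assignment(config: SimulationConfig) -> dict[str, list[str]]:
    """Experiment -> pooled donor lines, chunks of ``lines_per_pool``."""
    donors = _donor_ids(config)
    pools: dict[str, list[str]] = {}
    for e in range(config.n_experiments):
        start = e * config.lines_per_pool
        pools[f"expt{e:02d}"] = [
            donors[(start + j) % config.n_donors]
            for j in range(config.lines_per_pool)
        ]
    return pools


def gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene table (chrom, start, end, is_mt) for the simulated genome.

    Endogenous genes are spaced 1 Mb apart on one chromosome so that
    their cis windows do not overlap; a handful of mitochondrial genes
    (no variants) are appended for QC purposes.
    """
    ids = _gene_ids(config) + [f"MT-gene{i}" for i in range(N_MT_GENES)]
    n = len(ids)
    start = 1 + np.arange(n) * GENE_SPACING
    annot = pd.DataFrame(
        {
            "chrom": "1",
            "start": start,
            "end": start + GENE_LENGTH - 1,
            "is_mt": [False] * config.n_genes + [True] * N_MT_GENES,
        },
        index=pd.Index(ids, name="gene"),
    )
    return annot


def simulate_genotypes(config: SimulationConfig) -> PhasedGenotypes:
    """Draw phased genotypes for all cis and exonic SNPs.

    Each variant receives a generating allele frequency uniform in
    ``config.maf_range``; the two haplotype alleles of every donor are
    independent Bernoulli draws at that frequency. Cis SNPs are placed
    uniformly within +/-250 kb of the gene body, exonic (ASE) SNPs
    within the gene body itself.
    """
    rng = _rng(config, 1)
    annot = gene_annotation(config)
    endo = annot[~annot["is_mt"]]

    rows = []
    for gene, g in endo.iterrows():
        lo, hi = g["start"] - CIS_WINDOW, g["end"] + CIS_WINDOW
        pos_cis = np.sort(rng.integers(max(lo, 1), hi + 1, config.n_cis_snps_per_gene))
        for j, p in enumerate(pos_cis):
            rows.append((f"{gene}_snp{j}", g["chrom"], int(p), gene, False))
        pos_ase = np.sort(
            rng.integers(g["start"], g["end"] + 1, config.n_ase_snps_per_gene)
        )
        for j, p in enumerate(pos_ase):
            rows.append((f"{gene}_ase{j}", g["chrom"], int(p), gene, True))

    variants = pd.DataFrame(
        rows, columns=["variant", "chrom", "pos", "gene", "exonic"]
    ).set_index("variant")
    variants["ref"] = "A"
    variants["alt"] = "G"
    lo, hi = config.maf_range
    variants["gen_freq"] = rng.uniform(lo, hi, len(variants))

    hap = (
        rng.random((config.n_donors, len(variants), 2))
        < variants["gen_freq"].to_numpy()[None, :, None]
    ).astype(np.int8)
    geno = PhasedGenotypes(
        donors=_donor_ids(config),
        variants=variants[
            ["chrom", "pos", "ref", "alt", "gene", "exonic", "gen_freq"]
        ].copy(),
        haplotypes=hap,
    )
    geno.variants["maf"] = geno.realized_maf()
    return geno


def _day_beta_params(days: tuple[str, ...], concentration: float = 8.0):
    """Day-specific Beta(a, b) with means increasing along collection days."""
    k = len(days)
    means = (np.arange(k) + 0.5) / k
    return concentration * means, concentration * (1.0 - means)


def _assign_effects(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = _gene_ids(config)
    n = config.n_genes
    truth = pd.DataFrame(
        {
            "baseline": rng.uniform(3.0, 8.0, n),
            "traj_coef": 0.0,
            "module": "none",
            "eqtl_variant": "",
            "beta_static": 0.0,
            "beta_dynamic_slope": 0.0,
            "gxe_factor": -1,
            "gxe_effect": 0.0,
        },
        index=pd.Index(genes, name="gene"),
    )

    n_traj = min(config.n_trajectory_genes, n)
    traj_idx = np.arange(n_traj)
    signs = np.where(rng.random(n_traj) < 0.5, -1.0, 1.0)
    truth.iloc[traj_idx, truth.columns.get_loc("traj_coef")] = signs * rng.uniform(
        1.0, 2.0, n_traj
    )
    truth.iloc[traj_idx, truth.columns.get_loc("module")] = "trajectory"

    pos = n_traj
    for f in range(config.n_factors):
        idx = np.arange(pos, min(pos + config.n_factor_module_genes, n))
        truth.iloc[idx, truth.columns.get_loc("module")] = f"factor{f}"
        pos += config.n_factor_module_genes

    n_eqtl = int(round(config.frac_eqtl_genes * n))
    eqtl_idx = rng.choice(n, n_eqtl, replace=False)
    eqtl_signs = np.where(rng.random(n_eqtl) < 0.5, -1.0, 1.0)
    truth.iloc[eqtl_idx, truth.columns.get_loc("eqtl_variant")] = [
        f"{genes[i]}_snp0" for i in eqtl_idx
    ]
    truth.iloc[eqtl_idx, truth.columns.get_loc("beta_static")] = (
        eqtl_signs * config.beta_static
    )
    n_dyn = int(round(config.frac_dynamic * n_eqtl))
    dyn_idx = eqtl_idx[rng.choice(n_eqtl, n_dyn, replace=False)]
    truth.iloc[dyn_idx, truth.columns.get_loc("beta_dynamic_slope")] = (
        np.where(rng.random(n_dyn) < 0.5, -1.0, 1.0) * config.beta_dynamic_slope
    )
    n_gxe = int(round(config.frac_gxe * n_eqtl))
    gxe_idx = eqtl_idx[rng.choice(n_eqtl, n_gxe, replace=False)]
    truth.iloc[gxe_idx, truth.columns.get_loc("gxe_factor")] = rng.integers(
        0, config.n_factors, n_gxe
    )
    truth.iloc[gxe_idx, truth.columns.get_loc("gxe_effect")] = (
        np.where(rng.random(n_gxe) < 0.5, -1.0, 1.0) * config.gxe_factor_effect
    )
    return truth


def simulate_cells(
    config: SimulationConfig, genotypes: PhasedGenotypes
) -> tuple[ad.AnnData, pd.DataFrame, GroundTruth]:
    """Simulate the count matrix, metadata and ground truth.

    The log2-scale mean of each gene in each cell is the sum of a gene
    baseline, a trajectory term (coefficient x latent pseudotime), a
    donor effect, an experiment (batch) effect, the cis-eQTL term
    ``(beta_static + beta_dynamic_slope * pseudotime) * dosage`` and
    residual noise; relative weights ``2**mean`` are converted to
    per-cell expected counts and drawn negative-binomially.

    Returns ``(adata, metadata, truth)``; metadata is ``adata.obs``.
    """
    donors = _donor_ids(config)
    if list(genotypes.donors) != donors:
        raise ValueError("genotype donors do not match the simulation config")

    rng = _rng(config, 2)
    truth_genes = _assign_effects(config, rng)
    annot = gene_annotation(config)
    genes = list(annot.index)
    n_endo = config.n_genes

    pools = _pool_assignment(config)
    rows = []
    for expt, pool in pools.items():
        for donor in pool:
            for day in config.days:
                rows += [(donor, expt, day)] * config.cells_per_donor_day
    obs = pd.DataFrame(rows, columns=["donor", "experiment", "day"])
    obs.index = pd.Index([f"cell{i:05d}" for i in range(len(obs))], name="cell")
    n_cells = len(obs)

    a, b = _day_beta_params(config.days)
    day_idx = obs["day"].map({d: i for i, d in enumerate(config.days)}).to_numpy()
    conc = a + b
    day_mean = a / conc
    # line-specific differentiation rate shifts the day-specific
    # pseudotime mean on the logit scale
    donor_rate = rng.normal(0.0, config.donor_efficiency_sd, config.n_donors)
    donor_idx = obs["donor"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    from scipy.special import logit

    mean_dc = expit(logit(day_mean[day_idx]) + donor_rate[donor_idx])
    pseudotime = rng.beta(conc[day_idx] * mean_dc, conc[day_idx] * (1 - mean_dc))
    factors = rng.normal(size=(n_cells, config.n_factors))

    donor_eff = rng.normal(0.0, config.donor_sd, (config.n_donors, n_endo))
    batch_eff = rng.normal(0.0, config.batch_sd, (config.n_experiments, n_endo))
    d_of = obs["donor"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    e_of = (
        obs["experiment"].map({e: i for i, e in enumerate(pools)}).to_numpy()
    )

    log2rel = np.tile(truth_genes["baseline"].to_numpy(), (n_cells, 1))
    log2rel += pseudotime[:, None] * truth_genes["traj_coef"].to_numpy()[None, :]
    log2rel += donor_eff[d_of]
    log2rel += batch_eff[e_of]
    for f in range(config.n_factors):
        in_mod = (truth_genes["module"] == f"factor{f}").to_numpy()
        if in_mod.any():
            loading = rng.uniform(0.5, 1.0, in_mod.sum())
            log2rel[:, in_mod] += factors[:, [f]] * loading[None, :]

    dosage_all = genotypes.dosages()
    has_eqtl = truth_genes["eqtl_variant"] != ""
    for gi in np.flatnonzero(has_eqtl.to_numpy()):
        row = truth_genes.iloc[gi]
        dos = dosage_all[row["eqtl_variant"]].to_numpy()[d_of]
        log2rel[:, gi] += (
            row["beta_static"] + row["beta_dynamic_slope"] * pseudotime
        ) * dos
    log2rel += rng.normal(0.0, config.residual_sd, log2rel.shape)

    # mitochondrial genes: constant baseline, boosted in low-quality cells
    mt_rel = np.tile(rng.uniform(5.0, 7.0, N_MT_GENES), (n_cells, 1))
    low_q = rng.random(n_cells) < LOW_QUALITY_FRACTION
    mt_rel[low_q] += 3.0  # high MT fraction marks damaged cells
    weights = np.concatenate([2.0 ** log2rel, 2.0 ** mt_rel], axis=1)
    frac = weights / weights.sum(axis=1, keepdims=True)

    totals = config.mean_counts_per_cell * rng.lognormal(0.0, 0.2, n_cells)
    totals[low_q] *= 0.15
    mu = totals[:, None] * frac
    if config.nb_dispersion > 0:
        lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    donor_sex = dict(
        zip(donors, rng.choice(["female", "male"], size=config.n_donors))
    )
    obs["sex"] = obs["donor"].map(donor_sex)
    obs["mapping_rate"] = np.where(
        low_q, rng.uniform(0.30, 0.55, n_cells), rng.uniform(0.80, 0.98, n_cells)
    )
    obs["low_quality"] = low_q

    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=annot.loc[genes].copy(),
    )

    cell_truth = obs[["donor", "experiment", "day"]].copy()
    cell_truth["pseudotime"] = pseudotime
    cell_truth["donor_rate"] = donor_rate[donor_idx]
    for f in range(config.n_factors):
        cell_truth[f"factor{f}"] = factors[:, f]
    truth = GroundTruth(genes=truth_genes, cells=cell_truth, config=config)
    return adata, adata.obs, truth


def simulate_allelic_counts(
    truth: GroundTruth,
    genotypes: PhasedGenotypes,
    adata: ad.AnnData,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Draw per-cell per-SNP allelic read counts at exonic heterozygous SNPs.

    The gene's count in a cell is split uniformly (rounded share) across
    that donor's heterozygous exonic SNPs; each share is then split
    between the two haplotypes by a beta-binomial whose mean is logistic
    in ``ln(2) * (beta_static + beta_dynamic_slope * pseudotime) +
    gxe_effect * factor`` on the haplotype carrying the eQTL alternative
    allele. Donors homozygous at the eQTL variant receive a symmetric
    split. Only heterozygous (donor, SNP) pairs produce records.

    Returns a tidy frame with columns cell, donor, gene, snp, chrom,
    pos, ref, alt, ref_reads, alt_reads, total_reads.
    """
    config = config or truth.config
    rng = _rng(config, 3)
    variants = genotypes.variants
    exonic = variants[variants["exonic"]]
    donors = list(genotypes.donors)
    d_index = {d: i for i, d in enumerate(donors)}
    counts = np.asarray(adata.X)
    cell_donor_idx = np.array([d_index[d] for d in adata.obs["donor"]])
    pt = truth.cells.loc[adata.obs_names, "pseudotime"].to_numpy()
    conc = config.ase_overdispersion

    out = []
    for gene, gvars in exonic.groupby("gene", sort=True):
        gi = adata.var_names.get_loc(gene)
        gene_counts = counts[:, gi]
        row = truth.genes.loc[gene]
        snp_ids = list(gvars.index)
        snp_j = variants.index.get_indexer(snp_ids)
        het = (
            genotypes.haplotypes[:, snp_j, 0] != genotypes.haplotypes[:, snp_j, 1]
        )  # donors x snps
        n_het = het.sum(axis=1)

        # probability that a read comes from chrB, per donor
        p_chrb_donor = np.full(len(donors), 0.5)
        eff_static = LN2 * row["beta_static"]
        eff_slope = LN2 * row["beta_dynamic_slope"]
        if row["eqtl_variant"]:
            ej = variants.index.get_loc(row["eqtl_variant"])
            e_hap = genotypes.haplotypes[:, ej, :]
            e_het = e_hap[:, 0] != e_hap[:, 1]
            alt_on_chrb = e_hap[:, 1] == 1
        else:
            e_het = np.zeros(len(donors), dtype=bool)
            alt_on_chrb = np.zeros(len(donors), dtype=bool)

        for k, snp in enumerate(snp_ids):
            j = snp_j[k]
            cell_het = het[cell_donor_idx, k]
            cells = np.flatnonzero(cell_het & (n_het[cell_donor_idx] > 0))
            if cells.size == 0:
                continue
            share = np.rint(
                gene_counts[cells] / n_het[cell_donor_idx[cells]]
            ).astype(np.int64)
            keep = share > 0
            cells, share = cells[keep], share[keep]
            if cells.size == 0:
                continue

            cd = cell_donor_idx[cells]
            eff = np.zeros(cells.size)
            hetq = e_het[cd]
            if row["eqtl_variant"]:
                eff_alt_hap = eff_static + eff_slope * pt[cells]
                if row["gxe_factor"] >= 0:
                    fvals = truth.cells.iloc[cells][
                        f"factor{int(row['gxe_factor'])}"
                    ].to_numpy()
                    eff_alt_hap = eff_alt_hap + row["gxe_effect"] * fvals
                sign = np.where(alt_on_chrb[cd], 1.0, -1.0)
                eff = np.where(hetq, sign * eff_alt_hap, 0.0)
            p_chrb = expit(eff)

            if np.isinf(conc):
                chrb_reads = rng.binomial(share, p_chrb)
            else:
                p_cell = rng.beta(p_chrb * conc, (1.0 - p_chrb) * conc)
                chrb_reads = rng.binomial(share, p_cell)

            alt_on_chrb_snp = genotypes.haplotypes[cd, j, 1] == 1
            alt_reads = np.where(alt_on_chrb_snp, chrb_reads, share - chrb_reads)
            frame = pd.DataFrame(
                {
                    "cell": adata.obs_names[cells],
                    "donor": [donors[i] for i in cd],
                    "gene": gene,
                    "snp": snp,
                    "chrom": variants.iloc[j]["chrom"],
                    "pos": variants.iloc[j]["pos"],
                    "ref": variants.iloc[j]["ref"],
                    "alt": variants.iloc[j]["alt"],
                    "alt_reads": alt_reads,
                    "total_reads": share,
                }
            )
            out.append(frame)

    if not out:
        cols = [
            "cell", "donor", "gene", "snp", "chrom", "pos", "ref", "alt",
            "ref_reads", "alt_reads", "total_reads",
        ]
        return pd.DataFrame(columns=cols)
    result = pd.concat(out, ignore_index=True)
    result["ref_reads"] = result["total_reads"] - result["alt_reads"]
    cols = [
        "cell", "donor", "gene", "snp", "chrom", "pos", "ref", "alt",
        "ref_reads", "alt_reads", "total_reads",
    ]
    return result[cols].sort_values(["gene", "snp", "cell"], ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genotypes, cells, allelic counts."""
    genotypes = simulate_genotypes(config)
    adata, _, truth = simulate_cells(config, genotypes)
    allelic = simulate_allelic_counts(truth, genotypes, adata, config)
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        adata=adata,
        truth=truth,
        allelic_counts=allelic,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> dict:
    """Write the dataset to plain-text files and return a manifest.

    Emits a phased VCF, MatrixMarket counts with row/column name files,
    cell metadata, variant annotation, allelic counts, ground-truth
    tables and the config; the manifest maps each file to its sha256.
    """
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno, adata = dataset.genotypes, dataset.adata

    vcf_path = out / "genotypes.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.donors)
            + "\n"
        )
        order = np.argsort(geno.variants["pos"].to_numpy(), kind="stable")
        for j in order:
            v = geno.variants.iloc[j]
            gts = "\t".join(
                f"{geno.haplotypes[i, j, 0]}|{geno.haplotypes[i, j, 1]}"
                for i in range(geno.n_donors)
            )
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{geno.variants.index[j]}\t"
                f"{v['ref']}\t{v['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )

    from scipy import sparse

    mmwrite(out / "counts.mtx", sparse.csr_matrix(np.asarray(adata.X)))
    pd.Series(adata.obs_names).to_csv(out / "cells.txt", index=False, header=False)
    pd.Series(adata.var_names).to_csv(out / "genes.txt", index=False, header=False)
    adata.obs.to_csv(out / "metadata.tsv", sep="\t")
    adata.var.to_csv(out / "gene_annotation.tsv", sep="\t")
    geno.variants.to_csv(out / "variants.tsv", sep="\t")
    dataset.allelic_counts.to_csv(out / "allelic_counts.tsv", sep="\t", index=False)
    dataset.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    dataset.truth.cells.to_csv(out / "truth_cells.tsv", sep="\t")

    import yaml
    from dataclasses import asdict

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(dataset.config), fh, sort_keys=False)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {name: _sha256(out / name) for name in files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
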