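"""Configuration objects for simulation, QC and the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the pooled multi-donor differentiation simulator.

    Defaults are sized for desk-scale runs: 30 donors pooled 5 lines per
    experiment over 6 experiments, 4 collection days, 50 cells per donor
    and day, 200 genes.
    """

    n_donors: int = 30
    lines_per_pool: int = 5
    n_experiments: int = 6
    days: tuple[str, ...] = ("day0", "day1", "day2", "day3")
    cells_per_donor_day: int = 50
    n_genes: int = 200
    n_cis_snps_per_gene: int = 5
    maf_range: tuple[float, float] = (0.1, 0.5)
    #: log2-expression change per copy of the alternative allele
    beta_static: float = 0.5
    #: change of the allelic effect per unit pseudotime
    beta_dynamic_slope: float = 0.5
    #: allelic-fraction shift (logit scale) per unit of the cellular factor
    gxe_factor_effect: float = 0.5
    donor_sd: float = 0.3
    batch_sd: float = 0.2
    #: sd of the per-line differentiation rate (logit shift of the
    #: day-specific pseudotime mean); lines differ markedly in how far
    #: they progress by the last collection day
    donor_efficiency_sd: float = 0.4
    residual_sd: float = 0.5
    #: negative-binomial overdispersion alpha; var = mu + alpha * mu^2
    nb_dispersion: float = 0.1
    #: beta-binomial concentration; larger means closer to binomial
    ase_overdispersion: float = 50.0
    #: fraction of genes carrying a cis-eQTL
    frac_eqtl_genes: float = 0.5
    #: fraction of eQTL genes whose effect changes along pseudotime
    frac_dynamic: float = 0.3
    #: fraction of eQTL genes with a factor-dependent allelic shift
    frac_gxe: float = 0.3
    #: number of genes driven by the differentiation trajectory
    n_trajectory_genes: int = 60
    #: genes per latent cellular-factor module
    n_factor_module_genes: int = 20
    n_factors: int = 2
    #: exonic SNPs per gene usable for allelic quantification
    n_ase_snps_per_gene: int = 2
    mean_counts_per_cell: float = 100_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (4 <= self.lines_per_pool <= 6):
            raise ValueError("lines_per_pool must be in [4, 6]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in (
            "n_donors",
            "n_experiments",
            "cells_per_donor_day",
            "n_genes",
            "n_cis_snps_per_gene",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_donors % self.lines_per_pool and (
            self.n_donors // self.lines_per_pool >= self.n_experiments
        ):
            raise ValueError(
                "n_donors must allow pooling lines_per_pool lines per experiment"
            )


@dataclass
class QcThresholds:
    """Cell-level QC thresholds.

    A cell passes QC only if all five thresholds pass: endogenous counts,
    genes detected, fraction of counts in the top-100 genes, mitochondrial
    fraction and mapping rate.
    """

    min_endogenous_counts: float = 50_000.0
    min_genes_detected: int = 5_000
    max_top100_fraction: float = 0.90
    max_mt_fraction: float = 0.15
    min_mapping_rate: float = 0.60

    def __post_init__(self) -> None:
        for name in ("max_top100_fraction", "max_mt_fraction", "min_mapping_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_endogenous_counts <= 0 or self.min_genes_detected <= 0:
            raise ValueError("count thresholds must be positive")

    @classmethod
    def synthetic_defaults(cls) -> "QcThresholds":
        """Thresholds rescaled to the desk-scale synthetic gene universe.

        With only a few hundred simulated genes, the genes-detected and
        top-100-fraction criteria lose their meaning (the top 100 genes
        are essentially all genes), so they are relaxed; count, MT and
        mapping-rate thresholds keep their intent at the simulated
        sequencing depth.
        """
        return cls(
            min_endogenous_counts=10_000,
            min_genes_detected=50,
            max_top100_fraction=1.0,
            max_mt_fraction=0.15,
            min_mapping_rate=0.60,
        )


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Defaults mirror the analysis conventions this package implements:
    a +/-250 kb cis window, MAF > 5%, 1000 genotype permutations, 10
    expression PCs, pseudotime from the top 500 highly variable genes,
    sliding windows of 25% of cells stepping by 2.5%, ASE tests requiring
    at least 50 cells, FDR 10%, and at least 10 day-3 cells per
    (donor, experiment) for differentiation efficiency.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    cis_window: int = 250_000
    maf_min: float = 0.05
    n_perm: int = 1000
    n_expr_pcs: int = 10
    hvg_fdr: float = 0.01
    n_pseudotime_genes: int = 500
    window_frac: float = 0.25
    window_step: float = 0.025
    min_ase_cells: int = 50
    fdr: float = 0.10
    efficiency_min_cells: int = 10
    n_modules_top_genes: int = 8000
    n_dynamics_clusters: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        qc = QcThresholds(**raw.pop("qc", {}))
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, qc=qc, **raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
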