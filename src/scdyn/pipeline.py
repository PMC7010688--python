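"""End-to-end orchestration of the synthetic-data analysis pipeline.

Stages run in dependency order::

    simulate -> preprocess -> trajectory -> eqtl -> ase -> modules
             -> interactions -> efficiency

Each stage writes TSV outputs with a provenance header into the run
directory and appends in/out counts to ``run.log``. A stage whose
prerequisites were produced by an earlier invocation is reloaded from
disk; a missing prerequisite halts the run naming the stage and cause.
All randomness derives from ``PipelineConfig.seed``, so re-running with
the same seed reproduces every output bit for bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from scdyn import ase as ase_mod
from scdyn import coexpression as coex
from scdyn import efficiency as eff
from scdyn import eqtl as eqtl_mod
from scdyn import interactions as inter
from scdyn import preprocess as prep
from scdyn import synthdata
from scdyn import trajectory as traj
from scdyn.config import PipelineConfig
from scdyn.io import read_phased_vcf, read_tsv, write_tsv

STAGES = (
    "simulate", "preprocess", "trajectory", "eqtl", "ase", "modules",
    "interactions", "efficiency",
)

EQTL_STRATA = ("iPSC", "mesendo", "defendo")


class PipelineError(RuntimeError):
    """A stage failed or its prerequisites are missing."""


def _log(out: Path, msg: str) -> None:
    with open(out / "run.log", "a") as fh:
        fh.write(msg + "\n")


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, stages=None
) -> dict:
    """Run the requested stages; returns the in-memory context."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    ctx: dict = {"config": config, "out": out}
    for stage in stages:
        fn = globals()[f"_stage_{stage}"]
        try:
            fn(ctx)
        except PipelineError:
            raise
        except Exception as exc:  # halt with stage name and cause
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return ctx


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(ctx: dict) -> None:
    config: PipelineConfig = ctx["config"]
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    dataset = synthdata.simulate_dataset(sim_cfg)
    sim_dir = ctx["out"] / "sim"
    synthdata.write_fixture(dataset, sim_dir)
    ctx["dataset"] = dataset
    _log(
        ctx["out"],
        f"simulate: {dataset.adata.n_obs} cells, {dataset.adata.n_vars} genes, "
        f"{dataset.genotypes.n_variants} variants, "
        f"{len(dataset.allelic_counts)} allelic records",
    )


def _load_dataset(ctx: dict) -> None:
    sim_dir = ctx["out"] / "sim"
    if not (sim_dir / "genotypes.vcf").exists():
        raise PipelineError(
            "stage requires simulated data; run the 'simulate' stage first"
        )
    import anndata as ad

    from scdyn.io import read_counts

    genotypes = read_phased_vcf(sim_dir / "genotypes.vcf")
    ann = read_tsv(sim_dir / "variants.tsv")
    genotypes.variants = genotypes.variants.join(ann[["gene", "exonic"]])
    adata = read_counts(
        sim_dir / "counts.mtx", sim_dir / "cells.txt", sim_dir / "genes.txt"
    )
    adata.obs = read_tsv(sim_dir / "metadata.tsv").loc[adata.obs_names]
    adata.var = read_tsv(sim_dir / "gene_annotation.tsv").loc[adata.var_names]
    allelic = read_tsv(sim_dir / "allelic_counts.tsv", index_col=None)
    truth = synthdata.GroundTruth(
        genes=read_tsv(sim_dir / "truth_genes.tsv").fillna({"eqtl_variant": ""}),
        cells=read_tsv(sim_dir / "truth_cells.tsv"),
        config=ctx["config"].simulation,
    )
    truth.genes["eqtl_variant"] = truth.genes["eqtl_variant"].fillna("")
    ctx["dataset"] = synthdata.SimulatedDataset(
        config=ctx["config"].simulation,
        genotypes=genotypes,
        adata=adata,
        truth=truth,
        allelic_counts=allelic,
    )


def _stage_preprocess(ctx: dict) -> None:
    if "dataset" not in ctx:
        _load_dataset(ctx)
    config: PipelineConfig = ctx["config"]
    ds = ctx["dataset"]
    adata = ds.adata

    kept = prep.qc_filter_cells(adata, config.qc)
    post = adata[kept].copy()
    logcpm_all = pd.DataFrame(
        prep.normalize_log_cpm(np.asarray(post.X)),
        index=post.obs_names,
        columns=post.var_names,
    )
    counts_pre = pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    )
    expressed = prep.filter_expressed_genes(
        counts_pre,
        adata.obs["experiment"],
        logcpm_all,
        post.obs["experiment"],
    )
    expressed = expressed[~post.var.loc[expressed, "is_mt"].astype(bool)]
    logcpm = logcpm_all[expressed]
    hvg = prep.highly_variable_genes(
        logcpm, post.obs["experiment"], fdr=config.hvg_fdr
    )

    ctx["logcpm"] = logcpm
    ctx["meta"] = post.obs
    write_tsv(hvg, ctx["out"] / "hvg.tsv", seed=config.seed, fdr=config.hvg_fdr)
    write_tsv(logcpm, ctx["out"] / "logcpm.tsv", seed=config.seed)
    write_tsv(post.obs, ctx["out"] / "metadata_qc.tsv", seed=config.seed)
    _log(
        ctx["out"],
        f"preprocess: kept {len(kept)}/{adata.n_obs} cells, "
        f"{len(expressed)}/{adata.n_vars} expressed genes, "
        f"{int(hvg['fdr_pass'].sum())} HVGs",
    )


def _require_preprocess(ctx: dict) -> None:
    if "logcpm" in ctx:
        return
    path = ctx["out"] / "logcpm.tsv"
    if not path.exists():
        raise PipelineError(
            "stage requires normalised expression; run 'preprocess' first"
        )
    ctx["logcpm"] = read_tsv(path)
    ctx["meta"] = read_tsv(ctx["out"] / "metadata_qc.tsv")


def _stage_trajectory(ctx: dict) -> None:
    _require_preprocess(ctx)
    config: PipelineConfig = ctx["config"]
    hvg_path = ctx["out"] / "hvg.tsv"
    if not hvg_path.exists():
        raise PipelineError("trajectory requires the HVG table; run 'preprocess'")
    hvg = read_tsv(hvg_path)
    pt = traj.compute_pseudotime(
        ctx["logcpm"], hvg.index, ctx["meta"]["day"], config.n_pseudotime_genes
    )
    stage = traj.assign_stages(pt.pseudotime, ctx["meta"]["day"])
    windows = traj.sliding_windows(
        pt.pseudotime, config.window_frac, config.window_step
    )
    meta = ctx["meta"].copy()
    meta["pseudotime"] = pt.pseudotime
    meta["stage"] = stage.astype(str)
    ctx["meta"] = meta
    ctx["pseudotime"] = pt.pseudotime
    ctx["windows"] = windows
    write_tsv(meta, ctx["out"] / "metadata_traj.tsv", seed=config.seed)
    write_tsv(
        windows.membership(), ctx["out"] / "windows.tsv",
        seed=config.seed, frac=config.window_frac, step=config.window_step,
        index=False,
    )
    counts = stage.value_counts()
    _log(
        ctx["out"],
        "trajectory: stages "
        + ", ".join(f"{s}={int(counts.get(s, 0))}" for s in traj.STAGES),
    )


def _require_trajectory(ctx: dict) -> None:
    if "pseudotime" in ctx:
        return
    path = ctx["out"] / "metadata_traj.tsv"
    if not path.exists():
        raise PipelineError("stage requires pseudotime; run 'trajectory' first")
    meta = read_tsv(path)
    ctx["meta"] = meta
    ctx["pseudotime"] = meta["pseudotime"]
    config: PipelineConfig = ctx["config"]
    ctx["windows"] = traj.sliding_windows(
        meta["pseudotime"], config.window_frac, config.window_step
    )


def _stage_eqtl(ctx: dict) -> None:
    if "dataset" not in ctx:
        _load_dataset(ctx)
    _require_preprocess(ctx)
    _require_trajectory(ctx)
    config: PipelineConfig = ctx["config"]
    ds = ctx["dataset"]
    kinship = eqtl_mod.estimate_kinship(ds.genotypes)
    annot = ds.adata.var

    results = {}
    for i, stratum in enumerate(EQTL_STRATA):
        cells = ctx["meta"].index[ctx["meta"]["stage"] == stratum]
        if len(cells) == 0:
            continue
        agg = eqtl_mod.aggregate_expression(
            ctx["logcpm"].loc[cells], ctx["meta"].loc[cells], group_by="stage"
        )
        res = eqtl_mod.map_cis_eqtl(
            agg,
            ds.genotypes,
            annot,
            kinship,
            n_expr_pcs=config.n_expr_pcs,
            window=config.cis_window,
            maf_min=config.maf_min,
            n_perm=config.n_perm,
            seed=config.seed + i + 1,
        )
        results[stratum] = res
        write_tsv(
            res, ctx["out"] / f"eqtl_{stratum}.tsv", seed=config.seed,
            stratum=stratum, window=config.cis_window, maf=config.maf_min,
            n_perm=config.n_perm, pcs=config.n_expr_pcs, index=False,
        )
        n_egenes = int((res.loc[res["lead"], "q_value"] < config.fdr).sum())
        _log(
            ctx["out"],
            f"eqtl[{stratum}]: {res['gene'].nunique()} genes tested, "
            f"{n_egenes} eGenes at FDR {config.fdr:g}",
        )

    ctx["eqtl"] = results
    leads = []
    for stratum, res in results.items():
        lead = res[res["lead"]].copy()
        lead["stratum"] = stratum
        leads.append(lead)
    combined = pd.concat(leads, ignore_index=True)
    best = combined.sort_values(["gene", "p_adjusted", "p"]).groupby("gene").head(1)
    ctx["eqtl_leads"] = best.set_index("gene")

    if len(results) >= 2:
        strata = list(results)
        share = eqtl_mod.replicate_and_share(
            results[strata[0]][results[strata[0]]["lead"]], results[strata[1]]
        )
        write_tsv(
            share, ctx["out"] / "eqtl_sharing.tsv", seed=config.seed,
            strata=f"{strata[0]}-vs-{strata[1]}", index=False,
        )
        switches = eqtl_mod.detect_lead_switches(
            results, ds.genotypes, fdr=config.fdr
        )
        write_tsv(
            switches, ctx["out"] / "eqtl_lead_switches.tsv",
            seed=config.seed, index=False,
        )


def _require_eqtl(ctx: dict) -> None:
    if "eqtl_leads" in ctx:
        return
    paths = [
        ctx["out"] / f"eqtl_{s}.tsv" for s in EQTL_STRATA
        if (ctx["out"] / f"eqtl_{s}.tsv").exists()
    ]
    if not paths:
        raise PipelineError("stage requires eQTL leads; run 'eqtl' first")
    leads = []
    for p in paths:
        res = read_tsv(p, index_col=None)
        lead = res[res["lead"]].copy()
        leads.append(lead)
    combined = pd.concat(leads, ignore_index=True)
    best = combined.sort_values(["gene", "p_adjusted", "p"]).groupby("gene").head(1)
    ctx["eqtl_leads"] = best.set_index("gene")


def _stage_ase(ctx: dict) -> None:
    if "dataset" not in ctx:
        _load_dataset(ctx)
    _require_preprocess(ctx)
    _require_trajectory(ctx)
    _require_eqtl(ctx)
    config: PipelineConfig = ctx["config"]
    ds = ctx["dataset"]

    leads = ctx["eqtl_leads"]
    egenes = leads[leads["q_value"] < config.fdr]
    if egenes.empty:
        raise PipelineError("ase: no significant eGenes to quantify ASE against")
    eqtl_map = egenes["variant"]

    counts = ds.allelic_counts[
        ds.allelic_counts["cell"].isin(ctx["meta"].index)
    ]
    records = ase_mod.quantify_ase(counts, ds.genotypes, eqtl_map)
    binned = ase_mod.bin_ase_pseudotime(records, ctx["windows"])
    cpm = 2.0 ** ctx["logcpm"] - 1.0
    dynamics = ase_mod.allelic_expression_dynamics(
        binned, cpm, records, ctx["windows"]
    )
    ctx["ase_records"] = records
    ctx["ase_binned"] = binned
    write_tsv(records, ctx["out"] / "ase_records.tsv", seed=config.seed, index=False)
    write_tsv(binned, ctx["out"] / "ase_binned.tsv", seed=config.seed, index=False)
    write_tsv(
        dynamics, ctx["out"] / "ase_dynamics.tsv", seed=config.seed, index=False
    )
    _log(
        ctx["out"],
        f"ase: {len(records)} gene-level records across "
        f"{records['gene'].nunique()} eQTL",
    )


def _stage_modules(ctx: dict) -> None:
    _require_preprocess(ctx)
    config: PipelineConfig = ctx["config"]
    top = coex.select_top_expressed(ctx["logcpm"], config.n_modules_top_genes)
    modules = coex.affinity_propagation_modules(
        ctx["logcpm"][top], seed=config.seed
    )
    sizes = modules.membership.value_counts()
    chosen = list(sizes.index[:4])
    scores = coex.module_scores(ctx["logcpm"], modules, chosen)
    ctx["modules"] = modules
    ctx["factors"] = scores
    write_tsv(
        modules.membership.to_frame(), ctx["out"] / "modules.tsv",
        seed=config.seed,
    )
    write_tsv(scores, ctx["out"] / "factors.tsv", seed=config.seed)
    _log(
        ctx["out"],
        f"modules: {len(sizes)} modules over {len(top)} genes; "
        f"factor modules {chosen}",
    )


def _stage_interactions(ctx: dict) -> None:
    _require_preprocess(ctx)
    _require_trajectory(ctx)
    config: PipelineConfig = ctx["config"]
    if "ase_records" not in ctx:
        path = ctx["out"] / "ase_records.tsv"
        if not path.exists():
            raise PipelineError("interactions require ASE records; run 'ase'")
        ctx["ase_records"] = read_tsv(path, index_col=None)
        ctx["ase_binned"] = read_tsv(ctx["out"] / "ase_binned.tsv", index_col=None)
    if "factors" not in ctx:
        path = ctx["out"] / "factors.tsv"
        if not path.exists():
            raise PipelineError("interactions require factor scores; run 'modules'")
        ctx["factors"] = read_tsv(path)

    records = ctx["ase_records"]
    pt = ctx["pseudotime"]
    factors = ctx["factors"]

    dynamic = inter.bh_adjust(
        inter.test_dynamic(records, pt, config.min_ase_cells)
    )
    write_tsv(
        dynamic, ctx["out"] / "interactions_dynamic.tsv", seed=config.seed,
        index=False,
    )
    factor_results = []
    higher_results = []
    for name in factors.columns:
        f = factors[name]
        fam = inter.bh_adjust(
            inter.test_factor(records, pt, f, name, config.min_ase_cells)
        )
        factor_results.append(fam)
        hi = inter.bh_adjust(
            inter.test_higher_order(records, pt, f, name, config.min_ase_cells)
        )
        higher_results.append(hi)
    write_tsv(
        pd.concat(factor_results, ignore_index=True),
        ctx["out"] / "interactions_factor.tsv", seed=config.seed, index=False,
    )
    write_tsv(
        pd.concat(higher_results, ignore_index=True),
        ctx["out"] / "interactions_higher_order.tsv", seed=config.seed,
        index=False,
    )
    categories = inter.classify_eqtl(dynamic, factor_results, config.fdr)
    write_tsv(
        categories, ctx["out"] / "interactions_categories.tsv",
        seed=config.seed, index=False,
    )

    binned = ctx["ase_binned"]
    ase_prof = binned.pivot_table(
        index="gene", columns="window", values="mean_ase"
    ).dropna()
    genes = [g for g in ase_prof.index if g in ctx["logcpm"].columns]
    expr_prof = pd.DataFrame(
        {
            w.index: ctx["logcpm"].loc[w.cells, genes].mean(axis=0)
            for w in ctx["windows"]
        }
    )
    ase_prof = ase_prof.loc[genes]
    if len(genes) >= config.n_dynamics_clusters:
        expr_labels, ase_labels, _ = inter.cluster_dynamics(
            expr_prof, ase_prof, k=config.n_dynamics_clusters, seed=config.seed
        )
        clusters = pd.DataFrame(
            {"expression_cluster": expr_labels, "ase_cluster": ase_labels}
        )
        write_tsv(clusters, ctx["out"] / "dynamics_clusters.tsv", seed=config.seed)
    n_dyn = int((dynamic["p_bh"] < config.fdr).sum())
    _log(
        ctx["out"],
        f"interactions: {int((~dynamic['skipped']).sum())} eQTL tested, "
        f"{n_dyn} dynamic at FDR {config.fdr:g}",
    )
    ctx["interactions"] = {
        "dynamic": dynamic,
        "factor": factor_results,
        "higher_order": higher_results,
        "categories": categories,
    }


def _stage_efficiency(ctx: dict) -> None:
    if "dataset" not in ctx:
        _load_dataset(ctx)
    _require_preprocess(ctx)
    _require_trajectory(ctx)
    _require_eqtl(ctx)
    config: PipelineConfig = ctx["config"]
    ds = ctx["dataset"]

    records = eff.differentiation_efficiency(
        ctx["pseudotime"], ctx["meta"], config.efficiency_min_cells
    )
    write_tsv(
        records, ctx["out"] / "efficiency.tsv", seed=config.seed, index=False
    )

    leads = ctx["eqtl_leads"]
    egenes = leads[leads["q_value"] < config.fdr]
    dosages = ds.genotypes.dosages()
    results = []
    if not egenes.empty:
        genetic = dosages[
            [v for v in pd.unique(egenes["variant"]) if v in dosages.columns]
        ]
        genetic = genetic.loc[:, genetic.std(axis=0) > 0]
        if not genetic.empty:
            results.append(eff.test_marker_lmm(records, genetic, kind="genetic"))

    ipsc_cells = ctx["meta"].index[ctx["meta"]["stage"] == "iPSC"]
    if len(ipsc_cells):
        ipsc_expr = (
            ctx["logcpm"].loc[ipsc_cells]
            .groupby(ctx["meta"].loc[ipsc_cells, "donor"])
            .mean()
        )
        keep = ipsc_expr.columns[ipsc_expr.std(axis=0) > 0]
        markers = ipsc_expr[keep].reindex(pd.unique(records["donor"]))
        markers = markers.dropna(axis=0)
        records_expr = records[records["donor"].isin(markers.index)]
        if len(records_expr) and records_expr["experiment"].nunique() >= 2:
            results.append(
                eff.test_marker_lmm(records_expr, markers, kind="expression")
            )

    if "sex" in ctx["meta"].columns:
        donor_sex = (
            ctx["meta"][["donor", "sex"]].drop_duplicates().set_index("donor")["sex"]
        )
        if donor_sex.nunique() > 1:
            sex_res = eff.test_sex_effect(records, donor_sex)
            _log(
                ctx["out"],
                f"efficiency: sex effect {sex_res['effect']:.4g} "
                f"(p={sex_res['p']:.3g})",
            )

    if results:
        marker_table = pd.concat(results, ignore_index=True)
        write_tsv(
            marker_table, ctx["out"] / "efficiency_markers.tsv",
            seed=config.seed, index=False,
        )
        n_sig = int(marker_table["significant"].sum())
        _log(
            ctx["out"],
            f"efficiency: {len(records)} (donor, experiment) records, "
            f"{len(marker_table)} markers tested, {n_sig} significant",
        )
        ctx["efficiency_markers"] = marker_table
    ctx["efficiency"] = records
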