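"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF 4.x with phased GT; counts as MatrixMarket plus
row/column name files or as TSV; everything else is tab-separated text
with ``.`` for missing values and floats at 6 significant digits.
Result writers prepend a provenance header (version, seed, parameters)
as ``#`` comment lines.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import pysam

from scdyn.datatypes import PhasedGenotypes

TSV_NA = "."
FLOAT_FORMAT = "%.6g"


def read_phased_vcf(path: str | Path, on_multiallelic: str = "error") -> PhasedGenotypes:
    """Read a VCF with (mostly) phased GT into :class:`PhasedGenotypes`.

    Unphased entries are kept with their dosage but flagged, which
    excludes them from haplotype-aware (ASE) analyses. Multi-allelic
    records raise by default (``on_multiallelic="skip"`` drops them).
    """
    vf = pysam.VariantFile(str(path))
    donors = list(vf.header.samples)
    rows, haps, phased = [], [], []
    for i, rec in enumerate(vf.fetch() if vf.index else vf):
        if rec.alts is None or len(rec.alts) != 1:
            if on_multiallelic == "skip":
                continue
            raise ValueError(
                f"multi-allelic record at line {i + 1} "
                f"({rec.chrom}:{rec.pos}); pass on_multiallelic='skip'"
            )
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        rows.append((vid, str(rec.chrom), int(rec.pos), rec.ref, rec.alts[0]))
        h = np.zeros((len(donors), 2), dtype=np.int8)
        ph = np.zeros(len(donors), dtype=bool)
        for d, donor in enumerate(donors):
            call = rec.samples[donor]
            gt = call["GT"]
            if gt is None or None in gt or len(gt) != 2:
                raise ValueError(
                    f"malformed GT for {donor} at record {vid} (line {i + 1})"
                )
            h[d] = gt
            ph[d] = bool(call.phased)
        haps.append(h)
        phased.append(ph)
    if not rows:
        raise ValueError(f"no usable variant records in {path}")
    variants = pd.DataFrame(
        rows, columns=["variant", "chrom", "pos", "ref", "alt"]
    ).set_index("variant")
    return PhasedGenotypes(
        donors=donors,
        variants=variants,
        haplotypes=np.stack(haps, axis=1),
        phased=np.stack(phased, axis=1),
    )


def read_counts(
    path: str | Path,
    cells_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> ad.AnnData:
    """Read a cells x genes count matrix from MTX (+ name files) or TSV."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty counts file: {path}")
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if cells_path is None or genes_path is None:
            raise ValueError("MTX input needs cell and gene name files")
        x = np.asarray(mmread(str(path)).todense())
        cells = pd.read_csv(cells_path, header=None)[0].astype(str).tolist()
        genes = pd.read_csv(genes_path, header=None)[0].astype(str).tolist()
        if x.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {x.shape} does not match "
                f"{len(cells)} cells x {len(genes)} genes"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        x = df.to_numpy()
        cells, genes = df.index.astype(str).tolist(), df.columns.astype(str).tolist()
    adata = ad.AnnData(X=x.astype(np.int64))
    adata.obs_names = cells
    adata.var_names = genes
    return adata


def provenance_header(seed: int, **params) -> str:
    from scdyn import __version__

    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# scdyn {__version__} seed={seed} {items}".rstrip()


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    index: bool = True,
    **params,
) -> None:
    """Write a TSV with an optional provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(provenance_header(seed, **params) + "\n")
        df.to_csv(
            fh, sep="\t", na_rep=TSV_NA, float_format=FLOAT_FORMAT, index=index
        )


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=TSV_NA, index_col=index_col
    )
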