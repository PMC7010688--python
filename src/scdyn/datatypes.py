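"""Core in-memory containers shared across modules.

Expression data travels as :class:`anndata.AnnData` (cells as ``obs``,
genes as ``var``, raw counts in ``X`` and normalised values in
``layers["logcpm"]``); tabular results are plain :class:`pandas.DataFrame`
objects. Genotypes get a dedicated container because phase information
(two haplotype alleles per donor and variant) has no standard dense
in-memory type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class PhasedGenotypes:
    """Phased donor genotypes.

    Parameters
    ----------
    donors
        Donor identifiers, one per row of ``haplotypes``.
    variants
        One row per variant, indexed by variant id, with at least
        ``chrom``, ``pos``, ``ref`` and ``alt`` columns.
    haplotypes
        Array of shape ``(n_donors, n_variants, 2)`` with entries 0
        (reference) or 1 (alternative); ``[..., 0]`` is chrA and
        ``[..., 1]`` is chrB of the ``chrA|chrB`` phase notation.
    phased
        Boolean mask of shape ``(n_donors, n_variants)``; unphased
        entries keep their dosage but are excluded from haplotype-aware
        analyses.
    """

    donors: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray
    phased: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n_donors, n_variants, two = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (donors, variants, 2)")
        if n_donors != len(self.donors) or n_variants != len(self.variants):
            raise ValueError("haplotype dimensions do not match donors/variants")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        if self.phased is None:
            self.phased = np.ones((n_donors, n_variants), dtype=bool)
        self.phased = np.asarray(self.phased, dtype=bool)

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        donors: list[str] | None = None,
        variant_ids: list[str] | None = None,
        positions: np.ndarray | None = None,
        chrom: str = "1",
    ) -> "PhasedGenotypes":
        """Build phased genotypes from a donors x variants dosage matrix.

        Heterozygotes are phased alt-on-chrA; useful for dosage-level
        analyses (kinship, association) where phase carries no signal.
        """
        dosages = np.asarray(dosages)
        n_d, n_v = dosages.shape
        donors = donors or [f"d{i}" for i in range(n_d)]
        variant_ids = variant_ids or [f"v{j}" for j in range(n_v)]
        if positions is None:
            positions = 1000 * (np.arange(n_v) + 1)
        hap = np.zeros((n_d, n_v, 2), dtype=np.int8)
        hap[:, :, 0] = (dosages >= 1).astype(np.int8)
        hap[:, :, 1] = (dosages == 2).astype(np.int8)
        variants = pd.DataFrame(
            {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"},
            index=pd.Index(variant_ids, name="variant"),
        )
        return cls(donors=donors, variants=variants, haplotypes=hap)

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> pd.DataFrame:
        """Alternative-allele dosage (0/1/2) as donors x variants."""
        return pd.DataFrame(
            self.haplotypes.sum(axis=2),
            index=pd.Index(self.donors, name="donor"),
            columns=self.variant_ids,
            dtype=np.int8,
        )

    def dosage(self, variant_id: str) -> pd.Series:
        j = self.variants.index.get_loc(variant_id)
        return pd.Series(
            self.haplotypes[:, j, :].sum(axis=1),
            index=pd.Index(self.donors, name="donor"),
            name=variant_id,
        )

    def is_het(self, variant_id: str) -> pd.Series:
        j = self.variants.index.get_loc(variant_id)
        het = self.haplotypes[:, j, 0] != self.haplotypes[:, j, 1]
        return pd.Series(het, index=pd.Index(self.donors, name="donor"))

    def phase(self, donor: str, variant_id: str) -> str:
        """GT string, e.g. ``"0|1"`` (or ``"0/1"`` when unphased)."""
        i = self.donors.index(donor)
        j = self.variants.index.get_loc(variant_id)
        a, b = self.haplotypes[i, j]
        sep = "|" if self.phased[i, j] else "/"
        return f"{a}{sep}{b}"

    def realized_maf(self) -> pd.Series:
        """Minor allele frequency observed among the donors."""
        freq = self.haplotypes.sum(axis=(0, 2)) / (2 * self.n_donors)
        return pd.Series(
            np.minimum(freq, 1 - freq), index=self.variant_ids, name="maf"
        )

    def subset_variants(self, variant_ids) -> "PhasedGenotypes":
        idx = self.variants.index.get_indexer(variant_ids)
        if (idx < 0).any():
            raise KeyError("unknown variant id in subset")
        return PhasedGenotypes(
            donors=list(self.donors),
            variants=self.variants.iloc[idx].copy(),
            haplotypes=self.haplotypes[:, idx, :].copy(),
            phased=self.phased[:, idx].copy(),
        )
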