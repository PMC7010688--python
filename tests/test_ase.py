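"""Phased ASE quantification against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from scdyn.ase import (
    aggregate_ase_to_gene,
    allelic_expression_dynamics,
    bin_ase_pseudotime,
    orient_to_eqtl_alt,
    phase_to_haplotype_counts,
    quantify_ase,
)
from scdyn.datatypes import PhasedGenotypes
from scdyn.trajectory import sliding_windows


def _geno(phases: dict[str, dict[str, str]]) -> PhasedGenotypes:
    """Genotypes from explicit phase strings: donor -> variant -> 'a|b'."""
    donors = sorted(phases)
    variants = sorted({v for m in phases.values() for v in m})
    hap = np.zeros((len(donors), len(variants), 2), dtype=np.int8)
    phased = np.ones((len(donors), len(variants)), dtype=bool)
    for i, d in enumerate(donors):
        for j, v in enumerate(variants):
            gt = phases[d].get(v, "0|0")
            sep = "|" if "|" in gt else "/"
            a, b = gt.split(sep)
            hap[i, j] = (int(a), int(b))
            phased[i, j] = sep == "|"
    vdf = pd.DataFrame(
        {"chrom": "1", "pos": 100 * (np.arange(len(variants)) + 1),
         "ref": "A", "alt": "G"},
        index=pd.Index(variants, name="variant"),
    )
    return PhasedGenotypes(donors=donors, variants=vdf, haplotypes=hap,
                           phased=phased)


def _counts(rows):
    return pd.DataFrame(
        rows, columns=["cell", "donor", "gene", "snp", "alt_reads", "total_reads"]
    )


class TestPhaseConversion:
    def test_alt_on_chra(self):
        # phase 1|0: the alternative allele is on chrA, so chrB reads =
        # total - alt = 7
        geno = _geno({"d1": {"s1": "1|0"}})
        counts = _counts([("c1", "d1", "g1", "s1", 3, 10)])
        acc, rej = phase_to_haplotype_counts(counts, geno)
        assert acc.loc[0, "chrb_reads"] == 7
        assert rej.empty

    def test_alt_on_chrb(self):
        geno = _geno({"d1": {"s1": "0|1"}})
        counts = _counts([("c1", "d1", "g1", "s1", 3, 10)])
        acc, _ = phase_to_haplotype_counts(counts, geno)
        assert acc.loc[0, "chrb_reads"] == 3

    def test_rejections(self):
        geno = _geno({"d1": {"s1": "0|1", "s2": "1|1", "s3": "0/1"}})
        counts = _counts(
            [
                ("c1", "d1", "g1", "s1", 0, 0),   # no reads
                ("c1", "d1", "g1", "s2", 2, 5),   # homozygous
                ("c1", "d1", "g1", "s3", 2, 5),   # unphased
            ]
        )
        acc, rej = phase_to_haplotype_counts(counts, geno)
        assert acc.empty
        assert sorted(rej["reason"]) == ["homozygous", "no_reads", "unphased"]


class TestGeneAggregation:
    def test_additivity_and_commutativity(self):
        geno = _geno({"d1": {"s1": "0|1", "s2": "1|0"}})
        rows = [
            ("c1", "d1", "g1", "s1", 2, 4),
            ("c1", "d1", "g1", "s2", 5, 10),
        ]
        acc, _ = phase_to_haplotype_counts(_counts(rows), geno)
        agg = aggregate_ase_to_gene(acc)
        assert agg.loc[0, "chrb_reads"] == 2 + (10 - 5)
        assert agg.loc[0, "total_reads"] == 14
        acc_rev, _ = phase_to_haplotype_counts(_counts(rows[::-1]), geno)
        agg_rev = aggregate_ase_to_gene(acc_rev)
        pd.testing.assert_frame_equal(agg, agg_rev)

    def test_single_snp_passthrough(self):
        geno = _geno({"d1": {"s1": "0|1"}})
        acc, _ = phase_to_haplotype_counts(
            _counts([("c1", "d1", "g1", "s1", 3, 9)]), geno
        )
        agg = aggregate_ase_to_gene(acc)
        assert agg.loc[0, "chrb_reads"] == 3
        assert agg.loc[0, "total_reads"] == 9

    def test_unmapped_snp_ignored(self):
        geno = _geno({"d1": {"s1": "0|1", "s2": "0|1"}})
        acc, _ = phase_to_haplotype_counts(
            _counts([("c1", "d1", "g1", "s1", 3, 9),
                     ("c1", "d1", "gX", "s2", 1, 2)]), geno
        )
        snp_gene = pd.Series({"s1": "g1", "s2": np.nan})
        agg = aggregate_ase_to_gene(acc, snp_gene)
        assert len(agg) == 1 and agg.loc[0, "gene"] == "g1"


class TestOrientation:
    def test_eqtl_alt_on_chrb(self):
        geno = _geno({"d1": {"e1": "0|1"}})
        gene_counts = pd.DataFrame(
            {"cell": ["c1"], "donor": ["d1"], "gene": ["g1"],
             "chrb_reads": [7], "total_reads": [14]}
        )
        out = orient_to_eqtl_alt(gene_counts, geno, pd.Series({"g1": "e1"}))
        assert out.loc[0, "fraction"] == pytest.approx(0.5)

    def test_eqtl_alt_on_chra(self):
        geno = _geno({"d1": {"e1": "1|0"}})
        gene_counts = pd.DataFrame(
            {"cell": ["c1", "c2"], "donor": ["d1", "d1"], "gene": ["g1", "g1"],
             "chrb_reads": [7, 10], "total_reads": [14, 14]}
        )
        out = orient_to_eqtl_alt(gene_counts, geno, pd.Series({"g1": "e1"}))
        assert out.loc[0, "fraction"] == pytest.approx(0.5)
        assert out.loc[1, "fraction"] == pytest.approx(4 / 14)

    def test_homozygous_donor_dropped(self):
        geno = _geno({"d1": {"e1": "1|1"}})
        gene_counts = pd.DataFrame(
            {"cell": ["c1"], "donor": ["d1"], "gene": ["g1"],
             "chrb_reads": [7], "total_reads": [14]}
        )
        out = orient_to_eqtl_alt(gene_counts, geno, pd.Series({"g1": "e1"}))
        assert out.empty


def brute_force_ase(counts, geno, eqtl_variants):
    """Independent single-pass oracle over raw records."""
    out = {}
    donors = list(geno.donors)
    for _, r in counts.iterrows():
        d, snp, gene = r["donor"], r["snp"], r["gene"]
        if gene not in eqtl_variants.index:
            continue
        i = donors.index(d)
        j = geno.variants.index.get_loc(snp)
        sa, sb = geno.haplotypes[i, j]
        if sa == sb or not geno.phased[i, j] or r["total_reads"] <= 0:
            continue
        ej = geno.variants.index.get_loc(eqtl_variants[gene])
        ea, eb = geno.haplotypes[i, ej]
        if ea == eb or not geno.phased[i, ej]:
            continue
        # reads on the chromosome carrying the SNP's alt allele
        alt_chrom_of_snp = "B" if sb == 1 else "A"
        reads_b = r["alt_reads"] if alt_chrom_of_snp == "B" else (
            r["total_reads"] - r["alt_reads"])
        # chromosome carrying the eQTL alt allele
        eqtl_chrom = "B" if eb == 1 else "A"
        alt_reads = reads_b if eqtl_chrom == "B" else r["total_reads"] - reads_b
        key = (r["cell"], gene)
        a, t = out.get(key, (0, 0))
        out[key] = (a + alt_reads, t + r["total_reads"])
    return {k: a / t for k, (a, t) in out.items() if t > 0}


def random_fixture(seed):
    rng = np.random.default_rng(seed)
    donors = [f"d{i}" for i in range(3)]
    snps = ["s1", "s2", "s3", "e1", "e2"]
    phases = {
        d: {
            s: f"{rng.integers(0, 2)}{'|' if rng.random() > 0.1 else '/'}"
               f"{rng.integers(0, 2)}"
            for s in snps
        }
        for d in donors
    }
    geno = _geno(phases)
    eqtl = pd.Series({"g1": "e1", "g2": "e2"})
    snp_gene = {"s1": "g1", "s2": "g1", "s3": "g2"}
    rows = []
    for c in range(rng.integers(2, 10)):
        d = donors[rng.integers(0, 3)]
        for s in ["s1", "s2", "s3"]:
            if rng.random() < 0.3:
                continue
            total = int(rng.integers(0, 20))
            alt = int(rng.integers(0, total + 1)) if total else 0
            rows.append((f"c{c}", d, snp_gene[s], s, alt, total))
    return _counts(rows), geno, eqtl


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_exactly(self, seed):
        counts, geno, eqtl = random_fixture(seed)
        expected = brute_force_ase(counts, geno, eqtl)
        got = quantify_ase(counts, geno, eqtl)
        got_map = {
            (r["cell"], r["gene"]): r["fraction"] for _, r in got.iterrows()
        }
        assert got_map == expected

    def test_phase_flip_involution(self):
        counts, geno, eqtl = random_fixture(99)
        flipped = PhasedGenotypes(
            donors=list(geno.donors),
            variants=geno.variants.copy(),
            haplotypes=geno.haplotypes[:, :, ::-1].copy(),
            phased=geno.phased.copy(),
        )
        a = quantify_ase(counts, geno, eqtl)
        b = quantify_ase(counts, flipped, eqtl)
        key = ["cell", "gene"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(a) == len(b)
        assert np.allclose(merged["fraction_a"], merged["fraction_b"])


class TestBinning:
    def _records_pt(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        cells = [f"c{i:03d}" for i in range(n)]
        pt = pd.Series(rng.uniform(0, 1, n), index=cells)
        rec = pd.DataFrame(
            {
                "cell": cells,
                "donor": "d1",
                "gene": "g1",
                "variant": "e1",
                "alt_chrom_reads": 1,
                "total_reads": 2,
                "fraction": rng.uniform(0, 1, n),
            }
        )
        return rec, pt

    def test_constant_fraction(self):
        rec, pt = self._records_pt()
        rec["fraction"] = 0.5
        ws = sliding_windows(pt, 0.25, 0.25)
        binned = bin_ase_pseudotime(rec, ws)
        assert np.allclose(binned["mean_ase"], 0.5)
        assert np.allclose(binned["sd"], 0.0)

    def test_single_record_window_sem_missing(self):
        rec, pt = self._records_pt(n=8)
        rec = rec.iloc[:1]
        ws = sliding_windows(pt, 0.25, 0.25)
        binned = bin_ase_pseudotime(rec, ws)
        with_rec = binned[binned["n"] == 1]
        assert len(with_rec) >= 1
        assert with_rec["sem"].isna().all()

    def test_matches_groupby_oracle(self):
        rec, pt = self._records_pt(seed=5)
        ws = sliding_windows(pt, 0.25, 0.125)
        binned = bin_ase_pseudotime(rec, ws)
        frac = rec.set_index("cell")["fraction"]
        for w in ws:
            vals = frac.reindex(w.cells).dropna()
            row = binned[binned["window"] == w.index].iloc[0]
            assert row["mean_ase"] == pytest.approx(vals.mean())
            assert row["n"] == len(vals)

    def test_allelic_dynamics_conservation(self):
        rec, pt = self._records_pt(seed=7)
        ws = sliding_windows(pt, 0.5, 0.25)
        binned = bin_ase_pseudotime(rec, ws)
        cpm = pd.DataFrame(
            np.random.default_rng(0).uniform(50, 150, (len(pt), 1)),
            index=pt.index, columns=["g1"],
        )
        dyn = allelic_expression_dynamics(binned, cpm, rec, ws)
        assert len(dyn) == len(ws)
        total = dyn["alt_chrom_cpm"] + dyn["other_chrom_cpm"]
        assert np.allclose(total, dyn["mean_cpm"])

    def test_allelic_dynamics_multiplication(self):
        rec, pt = self._records_pt(seed=8)
        rec["fraction"] = 0.6
        ws = sliding_windows(pt, 0.5, 0.5)
        binned = bin_ase_pseudotime(rec, ws)
        cpm = pd.DataFrame(100.0, index=pt.index, columns=["g1"])
        dyn = allelic_expression_dynamics(binned, cpm, rec, ws)
        assert np.allclose(dyn["alt_chrom_cpm"], 60.0)
        assert np.allclose(dyn["other_chrom_cpm"], 40.0)


class TestSyntheticRecovery:
    def test_injected_shift_recovered(self, dataset):
        # genes with a static allelic effect and no dynamics: mean
        # fraction should sit near the logistic of the log2 effect
        ds = dataset
        truth = ds.truth.genes
        static = truth[
            (truth.beta_static != 0)
            & (truth.beta_dynamic_slope == 0)
            & (truth.gxe_factor < 0)
        ]
        eqtl = static["eqtl_variant"]
        records = quantify_ase(ds.allelic_counts, ds.genotypes, eqtl)
        from scipy.special import expit

        for gene, sub in records.groupby("gene"):
            expected = expit(np.log(2) * truth.loc[gene, "beta_static"])
            assert sub["fraction"].mean() == pytest.approx(expected, abs=0.05)
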