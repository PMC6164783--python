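import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinafam import gene_annotation as ga
from kinafam.io_formats import GeneModel, packaged_family_table, \
    packaged_subfamily_assignments


class TestReverseComplement:
    def test_basic(self):
        assert ga.reverse_complement("ATGC") == "GCAT"
        assert ga.reverse_complement("AANT") == "ANTT"

    def test_involution(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGT"), size=100))
        assert ga.reverse_complement(ga.reverse_complement(s)) == s


class TestExtractCds:
    # chr layout: pos 1-10 filler, CDS1 11-19 (ATGGCTGCT), intron,
    # CDS2 30-32 (TAA)
    GENOME = {"chr": "CCCCCCCCCC" + "ATGGCTGCT" + "GTCCCCCCAG" + "TAA"}

    def _gene(self, strand="+"):
        return GeneModel(gene_id="g", chromosome="chr", strand=strand,
                         exons=[(11, 19), (30, 32)],
                         cds_segments=[(11, 19), (30, 32)])

    def test_plus_strand(self):
        assert ga.extract_cds(self._gene("+"), self.GENOME) == "ATGGCTGCTTAA"

    def test_minus_strand(self):
        # same segments on minus strand: revcomp of the concatenation
        cds = ga.extract_cds(self._gene("-"), self.GENOME)
        assert cds == ga.reverse_complement("ATGGCTGCTTAA")

    def test_out_of_bounds(self):
        gene = GeneModel(gene_id="g", chromosome="chr", strand="+",
                         exons=[(11, 19), (30, 35)],
                         cds_segments=[(30, 35)])
        with pytest.raises(ValueError, match="bounds"):
            ga.extract_cds(gene, {"chr": "A" * 33})

    def test_missing_chromosome(self):
        with pytest.raises(ValueError, match="chromosome"):
            ga.extract_cds(self._gene(), {"other": "ACGT"})

    def test_no_cds(self):
        gene = GeneModel(gene_id="g", chromosome="chr", strand="+",
                         exons=[(11, 19)])
        with pytest.raises(ValueError, match="no CDS"):
            ga.extract_cds(gene, self.GENOME)

    def test_round_trip_on_toy_both_strands(self, toy):
        annotations = {g.gene_id: g for g in toy.annotation}
        truth = dict(zip(toy.truth.members.gene_id,
                         toy.truth.members.protein))
        strands = {annotations[gid].strand for gid in truth}
        assert strands == {"+", "-"}  # both orientations exercised
        for gid, protein in truth.items():
            cds = ga.extract_cds(annotations[gid], toy.genome)
            assert ga.translate(cds) == protein, gid


class TestTranslate:
    def test_simple(self):
        assert ga.translate("ATGGCTTAA") == "MA"  # stop not counted

    def test_no_stop(self):
        assert ga.translate("ATGGCT") == "MA"

    def test_internal_stop(self):
        with pytest.raises(ValueError, match="internal stop"):
            ga.translate("ATGTAAGCTTAA")

    def test_length_not_multiple(self):
        with pytest.raises(ValueError, match="divisible"):
            ga.translate("ATGGC")

    def test_ambiguous_codon(self):
        with pytest.raises(ValueError, match="ambiguous"):
            ga.translate("ATGGNTTAA")
        assert ga.translate("ATGGNTTAA", ambiguous="X") == "MX"

    def test_table1_arithmetic(self):
        # 1125 bp CDS -> 374 aa: reverse-translate then re-translate
        rng = np.random.default_rng(1)
        protein = "M" + "".join(rng.choice(list("ACDEFGHIKLNQRSTV"),
                                           size=373))
        from kinafam.synthetic_data import _reverse_translate
        cds = _reverse_translate(protein, rng)
        assert len(cds) == 1125
        assert ga.translate(cds) == protein
        assert len(ga.translate(cds)) == 1125 // 3 - 1


class TestMolecularWeight:
    def test_glycine(self):
        assert ga.molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_additivity(self):
        # concatenation forms one peptide bond: releases one water
        water = 18.0153
        a, b = "ACDEFGHIK", "LMNPQRSTVWY"
        assert ga.molecular_weight(a + b) == pytest.approx(
            ga.molecular_weight(a) + ga.molecular_weight(b) - water,
            abs=0.01)

    def test_nonstandard_residue(self):
        with pytest.raises(ValueError):
            ga.molecular_weight("ACX")


class TestIsoelectricPoint:
    def test_zero_charge_at_pi(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            pi = ga.isoelectric_point(p)
            assert abs(ga.net_charge(p, pi)) < 1e-3

    def test_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            p = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
            grid = np.arange(0.0, 14.0, 1e-4)
            charges = np.array([ga.net_charge(p, ph) for ph in grid])
            crossing = grid[np.argmax(charges <= 0)]
            assert ga.isoelectric_point(p) == pytest.approx(crossing,
                                                            abs=2e-4)

    def test_basic_vs_acidic(self):
        assert ga.isoelectric_point("M" + "K" * 20) > 9.5
        assert ga.isoelectric_point("M" + "D" * 20) < 4.5

    def test_charge_monotone_in_ph(self):
        p = "MKDHERFACDEKRY"
        charges = [ga.net_charge(p, ph) for ph in np.linspace(0, 14, 57)]
        assert all(a >= b for a, b in zip(charges, charges[1:]))

    def test_biopython_cross_check(self):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
        rng = np.random.default_rng(4)
        for _ in range(5):
            p = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
            assert abs(ga.isoelectric_point(p) - IsoelectricPoint(p).pi()) \
                < 0.5

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.permutations(list("MKDHERFACDEKRYWLS")))
    def test_composition_invariance(self, perm):
        # pI depends on composition (plus the first residue's N-term pKa)
        p = "M" + "".join(perm)
        q = "M" + "".join(sorted(perm))
        assert ga.isoelectric_point(p) == pytest.approx(
            ga.isoelectric_point(q), abs=1e-3)


class TestSummaries:
    def test_roster_exon_summary(self):
        rows = packaged_family_table()
        genes = [GeneModel(gene_id=r.name, chromosome=r.chromosome,
                           strand="+",
                           exons=[(1 + 10 * k, 4 + 10 * k)
                                  for k in range(r.exon_count)],
                           ) for r in rows]
        counts, (lo, hi) = ga.exon_summary(genes)
        assert (lo, hi) == (2, 29)
        assert counts["AcMAPK6"] == max(counts.values()) == 29

    def test_group_d_max_exons(self):
        asg = packaged_subfamily_assignments()
        rows = packaged_family_table()
        assert max(r.exon_count for r in rows if asg[r.name] == "D") == 11

    def test_chromosome_distribution(self):
        rows = packaged_family_table()
        dist = ga.chromosome_distribution(rows)
        assert sum(dist.values()) == 18
        assert len(dist) == 11

    def test_structure_tiling(self, toy):
        rows = ga.gene_structure_table(toy.annotation)
        by_gene = {}
        for r in rows:
            by_gene.setdefault(r["gene_id"], []).append(r)
        for gene in toy.annotation:
            feats = by_gene[gene.gene_id]
            span = gene.span
            assert feats[0]["start"] == span[0]
            assert feats[-1]["end"] == span[1]
            for a, b in zip(feats, feats[1:]):
                assert b["start"] == a["end"] + 1  # no gaps, no overlaps
            n_introns = sum(1 for f in feats if f["feature"] == "intron")
            assert n_introns == gene.exon_count - 1
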