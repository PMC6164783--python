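import math

import numpy as np
import pytest

from kinafam import kinase_scan, synthetic_data
from kinafam.kinase_scan import ScanConfig

from oracles import local_score_bruteforce


class TestSmithWaterman:
    def test_identity(self):
        from Bio.Align import substitution_matrices
        b62 = substitution_matrices.load("BLOSUM62")
        seq = "HEAGAWGHEE"
        score, (qs, ts) = kinase_scan.smith_waterman(seq, seq)
        assert score == sum(b62[a, a] for a in seq)
        assert qs == ts == (0, 10)

    def test_known_pair(self):
        # W-W (11) + identical flanking A-A (4): gap would cost >= 12
        score, _ = kinase_scan.smith_waterman("AWA", "AWA")
        assert score == 11 + 2 * 4

    def test_no_positive_alignment(self):
        score, spans = kinase_scan.smith_waterman("W", "P")
        assert score == 0 and spans == ((0, 0), (0, 0))

    def test_empty_sequence(self):
        with pytest.raises(ValueError, match="empty"):
            kinase_scan.smith_waterman("", "ACD")

    def test_bad_alphabet(self):
        with pytest.raises(ValueError, match="alphabet"):
            kinase_scan.smith_waterman("ACU", "ACD")

    def test_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        alphabet = list("ACDE")
        for _ in range(40):
            a = "".join(rng.choice(alphabet,
                                   size=int(rng.integers(1, 5))))
            b = "".join(rng.choice(alphabet,
                                   size=int(rng.integers(1, 5))))
            score, _ = kinase_scan.smith_waterman(a, b)
            assert score == local_score_bruteforce(a, b, 11, 1), (a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = "".join(rng.choice(list("ACDEFGHIKL"), size=12))
            b = "".join(rng.choice(list("ACDEFGHIKL"), size=15))
            assert kinase_scan.smith_waterman(a, b)[0] == \
                kinase_scan.smith_waterman(b, a)[0]


class TestEvalue:
    def test_closed_form(self):
        # E = m * n * 2^-S exactly
        assert kinase_scan.evalue(0, 10, 100) == pytest.approx(1000.0)
        assert kinase_scan.evalue(10, 32, 32) == pytest.approx(1.0)

    def test_monotone_in_score(self):
        es = [kinase_scan.evalue(s, 400, 5000) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_scales_with_search_space(self):
        assert kinase_scan.evalue(50, 400, 10000) == \
            pytest.approx(10 * kinase_scan.evalue(50, 400, 1000))

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            kinase_scan.evalue(-1, 10, 10)

    def test_no_overflow_for_large_scores(self):
        assert kinase_scan.evalue(5000, 400, 10**7) == 0.0


class TestBestHit:
    def test_self_is_best(self, toy):
        refs = {r.id: r.sequence for r in toy.references}
        member = toy.truth.members.iloc[0]
        rid, score, e = kinase_scan.best_hit(member.protein, refs)
        assert toy.ref_groups[rid] == member.group
        assert e < ScanConfig().evalue_cutoff

    def test_decoy_insignificant(self, toy):
        refs = {r.id: r.sequence for r in toy.references}
        random_decoy = next(r.sequence for r in toy.proteins
                            if toy.truth.decoys.get(r.id) ==
                            "random non-kinase protein")
        _, _, e = kinase_scan.best_hit(random_decoy, refs)
        assert e > ScanConfig().evalue_cutoff


class TestPssm:
    def test_pure_column_closed_form(self):
        cfg = ScanConfig(pseudocount=1e-9)
        pssm = kinase_scan.build_pssm(["A"] * 10, cfg)
        assert pssm[0, kinase_scan.AA_INDEX["A"]] == \
            pytest.approx(math.log2(1 / 0.05), abs=1e-6)

    def test_pseudocount_closed_form(self):
        pssm = kinase_scan.build_pssm(["W", "W"], ScanConfig(pseudocount=1.0))
        assert pssm[0, kinase_scan.AA_INDEX["W"]] == \
            pytest.approx(math.log2((3 / 22) / 0.05))
        assert pssm[0, kinase_scan.AA_INDEX["A"]] == \
            pytest.approx(math.log2((1 / 22) / 0.05))

    def test_uniform_counts_score_zero(self):
        pssm = kinase_scan.build_pssm(list(kinase_scan.AA))
        assert np.allclose(pssm, 0.0)

    @pytest.mark.parametrize("rows", [["A"], ["AC", "A"], ["A-", "AC"]])
    def test_bad_seed_alignment(self, rows):
        with pytest.raises(ValueError):
            kinase_scan.build_pssm(rows)

    def test_scan_consensus_hits_max(self):
        rows = ["HRDLK", "HRDLK", "HRDMK"]
        pssm = kinase_scan.build_pssm(rows)
        flank = "PPPPP"
        score, off = kinase_scan.pssm_scan(flank + "HRDLK" + flank, pssm)
        assert off == 5
        assert score == pytest.approx(float(pssm.max(axis=1).sum()))

    def test_scan_tie_smallest_offset(self):
        pssm = kinase_scan.build_pssm(["AC", "AC"])
        _, off = kinase_scan.pssm_scan("ACAC", pssm)
        assert off == 0

    def test_scan_short_protein(self):
        pssm = kinase_scan.build_pssm(["ACDEF", "ACDEF"])
        with pytest.raises(ValueError, match="shorter"):
            kinase_scan.pssm_scan("ACD", pssm)


class TestSignature:
    def _protein(self):
        s = synthetic_data
        return ("M" + "P" * 20 + s.ANCHOR_GXGXXG + "Q" * 15 + s.ANCHOR_VAIK
                + "N" * 15 + s.ANCHOR_HRD + "T" * 10 + s.ANCHOR_DFG
                + "C" * 8 + "TEY" + "C" * 8 + s.ANCHOR_APE + "S" * 20
                + s.ANCHOR_CD + "L" * 250)

    def test_full_signature(self):
        sig = kinase_scan.find_signature(self._protein())
        assert sig.anchors_found == {"GxGxxG", "VAIK", "HRD", "DFG", "APE",
                                     "CD"}
        assert sig.tloop_type == "TEY"
        # anchors must be found in N->C order
        order = ["GxGxxG", "VAIK", "HRD", "DFG", "APE"]
        pos = [sig.anchor_positions[n] for n in order]
        assert pos == sorted(pos)
        assert sig.anchor_positions["DFG"] < sig.tloop_pos < \
            sig.anchor_positions["APE"]
        assert sig.cd_span[0] > sig.anchor_positions["APE"]

    def test_position_covariance_under_prepend(self):
        base = self._protein()
        sig0 = kinase_scan.find_signature(base)
        sig4 = kinase_scan.find_signature("PPPP" + base)
        for name in sig0.anchor_positions:
            assert sig4.anchor_positions[name] == \
                sig0.anchor_positions[name] + 4
        assert sig4.tloop_pos == sig0.tloop_pos + 4

    def test_tloop_must_lie_between_dfg_and_ape(self):
        s = synthetic_data
        # T-loop placed after APE: no activation loop should be called
        prot = ("M" + "P" * 20 + s.ANCHOR_GXGXXG + "Q" * 15 + s.ANCHOR_VAIK
                + "N" * 15 + s.ANCHOR_HRD + "T" * 10 + s.ANCHOR_DFG
                + "C" * 8 + "CCC" + "C" * 8 + s.ANCHOR_APE + "TEY" + "S" * 20)
        sig = kinase_scan.find_signature(prot)
        assert sig.tloop_type == "none"

    def test_tdy_detected(self):
        prot = self._protein().replace("TEY", "TDY")
        assert kinase_scan.find_signature(prot).tloop_type == "TDY"


class TestValidate:
    def test_accept_planted(self, toy):
        for _, row in toy.truth.members.iterrows():
            ok, reasons = kinase_scan.validate_candidate(
                row.protein, hit_evalue=1e-120)
            assert ok and not reasons, (row.gene_id, reasons)

    def test_reject_all_decoys(self, toy):
        for rec in toy.proteins:
            if rec.id not in toy.truth.decoys:
                continue
            ok, reasons = kinase_scan.validate_candidate(
                rec.sequence, hit_evalue=1.0)
            assert not ok and reasons, rec.id

    def test_excised_tloop_reason(self, toy):
        excised = [rid for rid, why in toy.truth.decoys.items()
                   if "excised" in why]
        assert excised
        seqs = {r.id: r.sequence for r in toy.proteins}
        for rid in excised:
            ok, reasons = kinase_scan.validate_candidate(
                seqs[rid], hit_evalue=1e-120)
            assert not ok
            assert "no TEY/TDY activation-loop motif" in reasons

    def test_short_fragment(self, toy):
        fragment = toy.truth.members.iloc[0].protein[:250]
        ok, reasons = kinase_scan.validate_candidate(
            fragment, hit_evalue=1e-120)
        assert not ok and "short polypeptide" in reasons

    def test_insignificant_hit(self, toy):
        ok, reasons = kinase_scan.validate_candidate(
            toy.truth.members.iloc[0].protein, hit_evalue=1e-10)
        assert not ok
        assert reasons == ["no significant similarity to reference kinases"]

    def test_pssm_route_can_rescue(self, toy):
        ok, _ = kinase_scan.validate_candidate(
            toy.truth.members.iloc[0].protein, hit_evalue=1.0,
            pssm_bits=35.0)
        assert ok


class TestScanConfig:
    @pytest.mark.parametrize("kw", [{"gap_open": 0}, {"gap_extend": -1},
                                    {"evalue_cutoff": 0.0},
                                    {"pseudocount": 0.0}])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            ScanConfig(**kw)
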