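import numpy as np
import pytest

from kinafam import alignment_phylo as ap
from kinafam.kinase_scan import find_signature
from kinafam.phylotree import Node, midpoint_root

from oracles import global_score_bruteforce, random_additive_tree


class TestNeedlemanWunsch:
    def test_identity(self):
        score, ga, gb = ap.needleman_wunsch("HRDLK", "HRDLK")
        assert ga == gb == "HRDLK"

    def test_gapped_strings_ungap_to_inputs(self):
        a, b = "GEGSYGACDEFW", "GEGSYGW"
        score, ga, gb = ap.needleman_wunsch(a, b)
        assert ga.replace("-", "") == a and gb.replace("-", "") == b
        assert len(ga) == len(gb)

    def test_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        alphabet = list("ACDE")
        for _ in range(40):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(1, 4))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(1, 4))))
            score, _, _ = ap.needleman_wunsch(a, b)
            assert score == global_score_bruteforce(a, b, 11, 1), (a, b)

    def test_affine_gap_cost(self):
        # aligning X against a k-gap costs open + k*extend on top of matches
        score, ga, gb = ap.needleman_wunsch("AAWWAA", "AAAA")
        assert score == 4 * 4 - (11 + 2 * 1)
        assert ga == "AAWWAA" and gb.count("-") == 2


class TestProgressiveMsa:
    def test_single_sequence(self):
        msa = ap.progressive_msa({"a": "ACDE"})
        assert msa.rows == {"a": "ACDE"}

    def test_identical_sequences_no_gaps(self):
        msa = ap.progressive_msa({f"s{i}": "HRDLKACDEF" for i in range(4)})
        assert all("-" not in r for r in msa.rows.values())
        assert msa.width == 10

    def test_ungap_recovers_inputs(self, toy):
        seqs = {r.gene_id: r.protein
                for _, r in toy.truth.members.head(6).iterrows()}
        msa = ap.progressive_msa(seqs)
        for sid, s in seqs.items():
            assert msa.ungapped(sid) == s

    def test_two_sequences_match_pairwise(self):
        a, b = "GEGSYGACDEFW", "GEGSYGW"
        _, ga, gb = ap.needleman_wunsch(a, b)
        msa = ap.progressive_msa({"a": a, "b": b})
        assert (msa.rows["a"], msa.rows["b"]) == (ga, gb)

    def test_within_group_anchor_columns_align(self, toy):
        """Same-group members differ only by point substitutions, so the
        MSA must place the DFG anchor of every member in the same column."""
        grp = toy.truth.members[toy.truth.members.group == "A"]
        seqs = dict(zip(grp.gene_id, grp.protein))
        msa = ap.progressive_msa(seqs)
        cols = set()
        for sid, s in seqs.items():
            start = find_signature(s).anchor_positions["DFG"] - 1
            row = msa.rows[sid]
            ungapped = 0
            for col, c in enumerate(row):
                if c != "-":
                    if ungapped == start:
                        cols.add(col)
                        break
                    ungapped += 1
        assert len(cols) == 1

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            ap.MultipleAlignment(ids=["a", "b"],
                                 rows={"a": "AC-", "b": "AC"})


class TestPDistance:
    def _msa(self, rows):
        return ap.MultipleAlignment(ids=list(rows), rows=rows)

    def test_hand_examples(self):
        d = ap.p_distance(self._msa({"a": "ACDE", "b": "ACEE"}))
        assert d.matrix[0, 1] == pytest.approx(0.25)
        d = ap.p_distance(self._msa({"a": "ACDE", "b": "ACDE"}))
        assert d.matrix[0, 1] == 0.0

    def test_pairwise_deletion(self):
        d = ap.p_distance(self._msa({"a": "ACDE", "b": "AC-E"}))
        assert d.matrix[0, 1] == 0.0
        d = ap.p_distance(self._msa({"a": "AWDE", "b": "AC-E"}))
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns(self):
        with pytest.raises(ValueError, match="comparable"):
            ap.p_distance(self._msa({"a": "AC--", "b": "--DE"}))

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            ap.DistanceMatrix(ids=["a", "b"],
                              matrix=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive(self):
        # ((a:2,b:3):1,(c:4,d:5)) -> known pairwise path lengths
        ids = ["a", "b", "c", "d"]
        m = np.array([[0, 5, 7, 8],
                      [5, 0, 8, 9],
                      [7, 8, 0, 9],
                      [8, 9, 9, 0]], dtype=float)
        tree = ap.neighbor_joining(ap.DistanceMatrix(ids=ids, matrix=m))
        back = ap.tree_path_lengths(tree)
        order = [back.ids.index(i) for i in ids]
        assert np.allclose(back.matrix[np.ix_(order, order)], m, atol=1e-9)
        assert tree.bipartitions() == {frozenset({"c", "d"})}

    def test_random_additive_trees(self):
        rng = np.random.default_rng(17)
        for n in range(4, 9):
            ids, m, splits = random_additive_tree(n, rng)
            tree = ap.neighbor_joining(ap.DistanceMatrix(ids=ids, matrix=m))
            back = ap.tree_path_lengths(tree)
            order = [back.ids.index(i) for i in ids]
            assert np.allclose(back.matrix[np.ix_(order, order)], m,
                               atol=1e-9), n
            assert tree.bipartitions() == splits, n

    def test_three_taxa(self):
        m = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = ap.neighbor_joining(
            ap.DistanceMatrix(ids=["a", "b", "c"], matrix=m))
        back = ap.tree_path_lengths(tree)
        order = [back.ids.index(i) for i in ["a", "b", "c"]]
        assert np.allclose(back.matrix[np.ix_(order, order)], m)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            ap.neighbor_joining(ap.DistanceMatrix(
                ids=["a", "b"], matrix=np.zeros((2, 2))))

    def test_negative_branch_clamped(self):
        m = np.array([[0, 1, 10, 10],
                      [1, 0, 10, 10],
                      [10, 10, 0, 0.1],
                      [10, 10, 0.1, 0]], dtype=float)
        tree = ap.neighbor_joining(
            ap.DistanceMatrix(ids=list("abcd"), matrix=m))
        assert all((n.length or 0.0) >= 0.0 for n in tree.iter_nodes())


class TestBootstrap:
    def _two_clade_msa(self):
        rows = {f"a{i}": "AAAAAAAAAAAAAAAA" for i in range(3)}
        rows.update({f"b{i}": "CCCCCCCCCCCCCCCC" for i in range(3)})
        return ap.MultipleAlignment(ids=list(rows), rows=rows)

    def test_conserved_split_full_support(self):
        tree = ap.bootstrap_support(self._two_clade_msa(), n_reps=50, seed=1)
        supports = [n.support for n in tree.iter_nodes()
                    if n is not tree and not n.is_leaf
                    and n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_in_range(self, family_tree, toy):
        msa, _ = family_tree
        small_ids = [i for i in msa.ids if i.startswith("REF_")]
        sub = ap.MultipleAlignment(
            ids=small_ids, rows={i: msa.rows[i] for i in small_ids})
        tree = ap.bootstrap_support(sub, n_reps=30, seed=0)
        for n in tree.iter_nodes():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0

    def test_deterministic_under_seed(self):
        msa = self._two_clade_msa()
        t1 = ap.bootstrap_support(msa, n_reps=25, seed=42)
        t2 = ap.bootstrap_support(msa, n_reps=25, seed=42)
        from kinafam.io_formats import write_newick
        assert write_newick(t1) == write_newick(t2)

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            ap.bootstrap_support(self._two_clade_msa(), n_reps=0)


class TestMidpointRoot:
    def test_chain_tree_balanced(self):
        tree = Node(children=[
            Node(name="a", length=1.0),
            Node(children=[Node(name="b", length=1.0),
                           Node(name="c", length=7.0)], length=1.0)])
        rooted = midpoint_root(tree)
        from kinafam.phylotree import _leaf_depths
        depths = dict(_leaf_depths(rooted))
        # diameter path a..c has length 9; both ends must sit 4.5 deep
        assert depths["a"] == pytest.approx(4.5)
        assert depths["c"] == pytest.approx(4.5)

    def test_input_untouched(self):
        tree = Node(children=[
            Node(name="a", length=1.0),
            Node(children=[Node(name="b", length=1.0),
                           Node(name="c", length=7.0)], length=1.0)])
        from kinafam.io_formats import write_newick
        before = write_newick(tree)
        midpoint_root(tree)
        assert write_newick(tree) == before

    def test_leaves_preserved(self, family_tree):
        _, tree = family_tree
        rooted = midpoint_root(tree)
        assert sorted(rooted.leaf_names()) == sorted(tree.leaf_names())
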