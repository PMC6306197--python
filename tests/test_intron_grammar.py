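from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribointron import intron_grammar as ig
from ribointron import synthetic_data as synth
from ribointron.insert_map import InsertRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestMatchIupac:
    def test_modal_donor_matches_consensus(self):
        assert ig.match_iupac("GTDHNN", "GTAAGT")

    def test_all_n_pattern_matches_everything(self):
        assert all(
            ig.match_iupac("NNNNNN", "".join(w)) for w in product("ACGT", repeat=6)
        )

    def test_exactly_144_hexamers_match_donor(self):
        n = sum(ig.match_iupac("GTDHNN", "".join(w)) for w in product("ACGT", repeat=6))
        assert n == 144

    def test_window_n_strict_vs_lenient(self):
        assert not ig.match_iupac("GTDHNN", "GTANGT")
        assert ig.match_iupac("GTDHNN", "GTANGT", lenient_n=True)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ig.match_iupac("GT", "GTA")


class TestPyrimidineFraction:
    @pytest.mark.parametrize(
        "seg, frac", [("CTCTCT", 1.0), ("AAAA", 0.0), ("ACTT", 0.75)]
    )
    def test_values(self, seg, frac):
        assert ig.pyrimidine_fraction(seg) == frac

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ig.pyrimidine_fraction("")


class TestScanSpliceosomal:
    def test_constructed_intron_found(self, rng):
        var = "".join(rng.choice(list("ACGT"), size=60))
        insert = "GTAAGT" + var + "TTAAC" + "TCTTTCCTC" + "".join(
            rng.choice(list("ACGT"), size=10)
        ) + "TACAG"
        feats = ig.scan_spliceosomal(insert)
        assert feats is not None
        assert feats.donor == (0, "GTAAGT")
        assert feats.branch[1] == "TTAAC"
        assert feats.acceptor[1] == "TACAG"

    def test_too_short_returns_none(self):
        assert ig.scan_spliceosomal("GTAAGTTTAACTACAG") is None

    def test_sampler_output_always_accepted(self, rng):
        for _ in range(200):
            intron = synth.sample_spliceosomal_intron(rng)
            assert ig.scan_spliceosomal(intron) is not None

    def test_28s_terminal_hexamer_reported(self, rng):
        intron = synth.sample_spliceosomal_intron(rng, gene="28S")
        feats = ig.scan_spliceosomal(intron, gene="28S")
        assert feats.acceptor_28s_match

    @given(seq=dna)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_acceptance_implies_gt_ag_boundaries(self, seq):
        feats = ig.scan_spliceosomal(seq)
        if feats is not None:
            assert seq.startswith("GT")
            assert seq.endswith("AG")

    def test_boundary_mutation_rejected(self, rng):
        intron = synth.sample_spliceosomal_intron(rng)
        assert ig.scan_spliceosomal("AA" + intron[2:]) is None
        assert ig.scan_spliceosomal(intron[:-2] + "TT") is None


class TestClassifyInsert:
    def mk(self, length, complete=True):
        return InsertRecord(
            seq_id="s", col_span=(0, length), flank_pair=(10, 11),
            observed_len=length, complete=complete,
        )

    def test_long_grammarless_insert_is_group_i(self, rng):
        seq = "AA" + "".join(rng.choice(list("ACGT"), size=448))
        assert ig.classify_insert(self.mk(450), seq) == "GI"

    def test_donor_only_long_insert_is_ambiguous(self, rng):
        # spliceosomal 5' end but no downstream grammar: possible nested SP
        seq = "GTAATA" + "".join(rng.choice(list("AG"), size=386))
        assert ig.classify_insert(self.mk(392), seq) == "ambiguous"

    def test_generator_sp_intron_recovered(self, rng):
        seq = synth.sample_spliceosomal_intron(rng)
        assert ig.classify_insert(self.mk(len(seq)), seq) == "SP"

    def test_generator_gi_intron_recovered(self, rng):
        seq = synth.sample_group1_intron(rng)
        assert ig.classify_insert(self.mk(len(seq)), seq) == "GI"

    def test_truncated_insert_partial(self, rng):
        seq = synth.sample_spliceosomal_intron(rng)[:40]
        assert ig.classify_insert(self.mk(40, complete=False), seq) == "partial(SP-like)"
        assert ig.classify_insert(self.mk(40, complete=False), "AAAA" + seq[4:]) == "partial"

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            ig.classify_insert(None, "")


class TestConservedBlocks:
    def test_identical_pair_fully_retained(self):
        s = "ACGTACGTACGTACGTACGT"
        out = ig.extract_conserved_blocks({"a": s, "b": s})
        assert out["a"] == s

    def test_block_structure_recovered_within_window(self, rng):
        block1 = "".join(rng.choice(list("ACGT"), size=30))
        block2 = "".join(rng.choice(list("ACGT"), size=30))
        mid_a = "".join(rng.choice(list("ACGT"), size=100))
        mid_b = "".join(rng.choice(list("ACGT"), size=100))
        a, b = block1 + mid_a + block2, block1 + mid_b + block2
        out = ig.extract_conserved_blocks({"a": a, "b": b}, window=10, min_identity=0.7)
        # retained columns approximate the two blocks, boundary within one window
        assert 40 <= len(out["a"]) <= 80
        assert out["a"].startswith(block1[:20])
        assert out["a"].endswith(block2[-20:])

    def test_random_pair_nearly_empty(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=200))
        out = ig.extract_conserved_blocks({"a": a, "b": b}, min_identity=0.7)
        assert len(out["a"]) < 30

    def test_shared_template_introns_share_blocks(self, rng):
        template = "".join(rng.choice(list("ACGT"), size=200))
        x = synth.sample_group1_intron(rng, ancestral_core=template)
        y = synth.sample_group1_intron(rng, ancestral_core=template)
        assert x != y  # spacers differ
        # conserved blocks exist in both (identity over blocks >= 1 - 2*mut)
        assert len(x) >= 399 and len(y) >= 399

    def test_single_sequence_errors(self):
        with pytest.raises(ValueError):
            ig.extract_conserved_blocks({"a": "ACGT"})


class TestDistances:
    def test_p_distance_values(self):
        assert ig.p_distance("ACGT", "ACGT") == 0.0
        assert ig.p_distance("ACGT", "ACGA") == 0.25

    def test_gap_and_n_skipped(self):
        assert ig.p_distance("AC-T", "ACNT") == 0.0

    def test_no_comparable_sites_errors(self):
        with pytest.raises(ValueError):
            ig.p_distance("--", "AC")

    @given(a=st.text("ACGT", min_size=4, max_size=4), b=st.text("ACGT", min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetry(self, a, b):
        assert ig.p_distance(a, b) == ig.p_distance(b, a)


def random_additive_tree(rng, n):
    from skbio import TreeNode

    nodes = [
        TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 0.5))) for i in range(n)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.05, 0.5))
        )
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    return nodes[0]


def tree_distances(tree, labels):
    n = len(labels)
    d = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = tips[labels[a]].distance(tips[labels[b]])
    return d


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = ig.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        )
        tree = ig.nj_tree(dm)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths["A"] == pytest.approx(0.05, abs=1e-12)
        assert lengths["B"] == pytest.approx(0.15, abs=1e-12)
        assert lengths["C"] == pytest.approx(0.25, abs=1e-12)

    def test_additive_matrices_recover_topology_and_lengths(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            tree = random_additive_tree(rng, n)
            labels = [f"t{i}" for i in range(n)]
            d = tree_distances(tree, labels)
            est = ig.nj_tree(ig.DistanceMatrix(labels, d))
            assert est.compare_rfd(tree) == 0
            d_est = tree_distances(est, labels)
            assert np.allclose(d_est, d, atol=1e-9)

    def test_agrees_with_independent_nj(self):
        import skbio

        rng = np.random.default_rng(3)
        n = 6
        tree = random_additive_tree(rng, n)
        labels = [f"t{i}" for i in range(n)]
        d = tree_distances(tree, labels)
        mine = ig.nj_tree(ig.DistanceMatrix(labels, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
        assert mine.compare_rfd(theirs) == 0

    def test_star_distances_deterministic(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0.0)
        dm = ig.DistanceMatrix(list("ABCD"), d)
        t1 = ig.nj_tree(dm).__str__()
        t2 = ig.nj_tree(dm).__str__()
        assert t1 == t2

    def test_fewer_than_three_taxa_errors(self):
        dm = ig.DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError):
            ig.nj_tree(dm)
        pair = ig.pair_tree(dm)
        assert {t.name for t in pair.tips()} == {"A", "B"}

    def test_negative_branch_clamped_with_warning(self):
        # triangle-inequality violation forces a negative terminal estimate
        d = np.array([[0, 0.1, 0.15], [0.1, 0, 0.4], [0.15, 0.4, 0]])
        dm = ig.DistanceMatrix(list("ABC"), d)
        with pytest.warns(UserWarning, match="clamped"):
            tree = ig.nj_tree(dm)
        assert all((n.length or 0) >= 0 for n in tree.traverse(include_self=False))

    def test_gi_introns_cluster_by_ancestral_lineage(self, rng):
        # introns diversified from two distinct ancestors form two clades,
        # mirroring the two within-family groups seen at separate locations
        def mutate(seq, rate):
            chars = list(seq)
            for i in range(len(chars)):
                if rng.random() < rate:
                    chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
            return "".join(chars)

        base1 = synth.sample_group1_intron(rng)
        base2 = synth.sample_group1_intron(rng)
        seqs = {}
        for k in range(3):
            seqs[f"loc4_{k}"] = mutate(base1, 0.05)
            seqs[f"loc12_{k}"] = mutate(base2, 0.05)
        L = min(map(len, seqs.values()))
        dm = ig.distance_matrix({k: v[:L] for k, v in seqs.items()})
        tree = ig.nj_tree(dm)
        from ribointron.barcode_eval import is_monophyletic

        assert is_monophyletic(tree, {"loc4_0", "loc4_1", "loc4_2"})
        assert is_monophyletic(tree, {"loc12_0", "loc12_1", "loc12_2"})
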