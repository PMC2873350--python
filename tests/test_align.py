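"""Pairwise alignment: worked examples, brute-force oracle, symmetry,
guide trees and the progressive aligner."""

import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from famkit import (AlignParams, SeqRecord, blosum62, build_guide_tree,
                    global_align, identity_pair, progressive_msa,
                    score_alignment)
from famkit.errors import AlignmentError, PhyloError
from famkit.phylo import DistanceMatrix


def brute_force_score(a: str, b: str, params: AlignParams) -> float:
    """Exhaustive enumeration over every global alignment (lattice path),
    scoring gaps as open + (k-1)*extend.  Independent of the Gotoh code."""
    best = [-float("inf")]

    def rec(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + params.matrix.score(a[i], b[j]))
        if i < len(a):
            cost = params.gap_extend if last == "X" else params.gap_open
            rec(i + 1, j, "X", score - cost)
        if j < len(b):
            cost = params.gap_extend if last == "Y" else params.gap_open
            rec(i, j + 1, "Y", score - cost)

    rec(0, 0, None, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_ef1_loop_self_alignment_scores_sum_of_diagonal(self, params):
        # independent oracle: sum the published BLOSUM62 diagonal entries
        loop = "DKDGDGTITTKE"
        raw = substitution_matrices.load("BLOSUM62")
        expected = sum(raw[c, c] for c in loop)
        assert expected == 64
        pw = global_align(SeqRecord(id="a", residues=loop),
                          SeqRecord(id="b", residues=loop), params)
        assert pw.score == expected
        assert "-" not in pw.a.gapped + pw.b.gapped

    def test_two_residue_alignment(self, params):
        pw = global_align(SeqRecord(id="a", residues="MK"),
                          SeqRecord(id="b", residues="MK"), params)
        assert pw.score == 10.0  # M:5 + K:5 on the BLOSUM62 diagonal

    def test_score_matches_exhaustive_enumeration(self, params):
        rnd = random.Random(20260924)
        for _ in range(30):
            a = "".join(rnd.choice("ACDE")
                        for _ in range(rnd.randint(1, 8)))
            b = "".join(rnd.choice("ACDE")
                        for _ in range(rnd.randint(1, 8)))
            pw = global_align(SeqRecord(id="a", residues=a),
                              SeqRecord(id="b", residues=b), params)
            assert pw.score == brute_force_score(a, b, params), (a, b)

    def test_emitted_alignment_rescored_consistently(self, params):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aas, size=rng.integers(5, 40)))
            b = "".join(rng.choice(aas, size=rng.integers(5, 40)))
            pw = global_align(SeqRecord(id="a", residues=a),
                              SeqRecord(id="b", residues=b), params)
            assert score_alignment(pw.a.gapped, pw.b.gapped, params) \
                == pw.score

    def test_symmetry(self, params):
        a = SeqRecord(id="a", residues="MKDGDGTITTKE")
        b = SeqRecord(id="b", residues="MKDGTTKE")
        fwd = global_align(a, b, params)
        rev = global_align(b, a, params)
        assert fwd.score == rev.score
        assert (fwd.a.gapped, fwd.b.gapped) == (rev.b.gapped, rev.a.gapped)

    def test_x_scores_zero_against_everything(self):
        m = blosum62()
        for aa in "ACDEFGHIKLMNPQRSTVWYX":
            assert m.score("X", aa) == 0

    def test_nucleotide_input_rejected(self, params):
        nt = SeqRecord(id="n", residues="ACGTACGT", moltype="nucleotide")
        aa = SeqRecord(id="p", residues="MKV")
        with pytest.raises(AlignmentError):
            global_align(nt, aa, params)


class TestGuideTree:
    def test_two_taxa_cherry(self):
        dm = DistanceMatrix(labels=["A", "B"],
                            values=np.array([[0.0, 2.0], [2.0, 0.0]]))
        t = build_guide_tree(dm)
        assert sorted(t.leaf_names()) == ["A", "B"]
        assert all(c.length == 1.0 for c in t.children)

    def test_minimum_pair_joined_first(self):
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float))
        t = build_guide_tree(dm)
        cherries = [set(n.leaf_names()) for n in t.walk()
                    if not n.is_leaf and n is not t]
        assert {"A", "B"} in cherries

    def test_ultrametric_input_recovered_exactly(self):
        # cophenetic distances of ((A:1,B:1):2,(C:2,D:2):1)
        labels = ["A", "B", "C", "D"]
        values = np.array([[0, 2, 6, 6],
                           [2, 0, 6, 6],
                           [6, 6, 0, 4],
                           [6, 6, 4, 0]], dtype=float)
        t = build_guide_tree(DistanceMatrix(labels=labels, values=values))
        paths = t.path_lengths()
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert paths[(a, b)] == pytest.approx(
                    values[i, labels.index(b)])

    def test_invalid_distances_rejected(self):
        with pytest.raises(PhyloError):
            build_guide_tree(DistanceMatrix(
                labels=["A", "B"], values=np.array([[0.0, np.nan],
                                                    [np.nan, 0.0]])))


class TestProgressiveMSA:
    def test_identical_sequences_align_gapless(self, params):
        recs = [SeqRecord(id=f"s{i}", residues="MKDGDGTITTKE")
                for i in range(5)]
        msa = progressive_msa(recs, params)
        assert all("-" not in r.gapped for r in msa.rows)
        assert len({r.gapped for r in msa.rows}) == 1

    def test_single_gap_placed_in_shorter_row(self, params):
        msa = progressive_msa([SeqRecord(id="a", residues="ACDE"),
                               SeqRecord(id="b", residues="ACE")], params)
        assert msa.n_columns == 4
        assert identity_pair(msa.rows[0], msa.rows[1]) == pytest.approx(75.0)

    def test_row_order_equals_input_order(self, params):
        recs = [SeqRecord(id="z", residues="MKVLDKDGDGTITTKE"),
                SeqRecord(id="a", residues="MKVLDADGNGTIDFPE"),
                SeqRecord(id="m", residues="DKDGDGTITTKE")]
        msa = progressive_msa(recs, params)
        assert msa.ids == ["z", "a", "m"]

    def test_duplicate_sequence_does_not_disturb_gap_pattern(self, params):
        recs = [SeqRecord(id="a", residues="MKVLDKDGDGTITTKE"),
                SeqRecord(id="b", residues="MKDKDGDGTITTKE"),
                SeqRecord(id="c", residues="MKVLDADGNGTIDFPE")]
        base = progressive_msa(recs, params)
        extended = progressive_msa(
            recs + [SeqRecord(id="a2", residues=recs[0].residues)], params)
        base_gaps = {r.id: tuple(i for i, c in enumerate(r.gapped)
                                 if c == "-") for r in base.rows}
        ext_gaps = {r.id: tuple(i for i, c in enumerate(r.gapped)
                                if c == "-") for r in extended.rows
                    if r.id != "a2"}
        assert base_gaps == ext_gaps

    def test_single_record_rejected(self, params):
        with pytest.raises(AlignmentError, match="unaligned"):
            progressive_msa([SeqRecord(id="a", residues="MKV")], params)
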