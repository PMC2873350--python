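"""Tree building: trimming, distances, NJ (with a dendropy oracle),
bootstrap reproducibility, consensus vs brute-force counting, rooting."""

import math
from collections import Counter

import dendropy
import numpy as np
import pytest

from famkit import (MultipleAlignment, SeqRecord, bootstrap_trees,
                    majority_consensus, nj_tree, p_distance, parse_newick,
                    root_on_outgroup, trim_variable_termini)
from famkit.errors import PhyloError
from famkit.phylo import DistanceMatrix
from famkit.seqio import AlignedRecord


def aln(rows: dict[str, str]) -> MultipleAlignment:
    return MultipleAlignment(rows=[
        AlignedRecord(record=SeqRecord(id=k, residues=v.replace("-", "")),
                      gapped=v) for k, v in rows.items()])


class TestTrim:
    def test_nterm_overhang_removed(self):
        msa = aln({"long": "MKVLMKVLMKDKDGDGTITT",
                   "ref": "----------DKDGDGTITT"})
        trimmed = trim_variable_termini(msa, "ref")
        assert trimmed.n_columns == 10
        assert trimmed.row("ref").gapped == "DKDGDGTITT"

    def test_identity_when_reference_spans_all(self):
        msa = aln({"a": "DKDGDGTITT", "ref": "DKDGDGTITT"})
        trimmed = trim_variable_termini(msa, "ref")
        assert [r.gapped for r in trimmed.rows] == \
            [r.gapped for r in msa.rows]

    def test_cterm_trim_drops_reference_overhang(self):
        msa = aln({"a": "MK--VEDE", "ref": "MKDGVE--"})
        trimmed = trim_variable_termini(msa, "ref", trim_cterm=True)
        # columns where only 'a' extends past the reference end are gone
        assert trimmed.n_columns == 6
        assert trimmed.row("ref").gapped == "MKDGVE"
        assert trimmed.row("a").gapped == "MK--VE"

    def test_missing_reference_rejected(self):
        msa = aln({"a": "MKVE", "b": "MKVE"})
        with pytest.raises(PhyloError):
            trim_variable_termini(msa, "nope")


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance(aln({"a": "MKVE", "b": "MKVE"}))
        assert dm.get("a", "b") == 0.0

    def test_p_distance_arithmetic(self):
        dm = p_distance(aln({"a": "AAAA", "b": "AAAC"}))
        assert dm.get("a", "b") == pytest.approx(0.25)

    def test_poisson_correction_closed_form(self):
        dm = p_distance(aln({"a": "AAAA", "b": "AAAC"}), poisson=True)
        assert dm.get("a", "b") == pytest.approx(-math.log(0.75))


class TestNeighborJoining:
    def test_three_taxon_star_lengths(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                            dtype=float))
        t = nj_tree(dm)
        lengths = {n.label: n.length for n in t.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_matrix_recovered_exactly(self):
        # path metric of ((A:1,B:1):1,(C:1,D:1):1)
        labels = ["A", "B", "C", "D"]
        values = np.array([[0, 2, 3, 3],
                           [2, 0, 3, 3],
                           [3, 3, 0, 2],
                           [3, 3, 2, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(labels=labels, values=values))
        assert t.bipartitions() == {frozenset({"C", "D"})}
        paths = t.path_lengths()
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert paths[(a, b)] == pytest.approx(
                    values[i, labels.index(b)], abs=1e-9)

    def test_topology_matches_dendropy_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            labels = [f"t{k}" for k in range(n)]
            # random additive-ish noise on a random tree metric
            base = rng.uniform(0.1, 1.0, size=(n, n))
            values = (base + base.T) / 2
            np.fill_diagonal(values, 0.0)
            ours = nj_tree(DistanceMatrix(labels=labels, values=values))
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_csv(labels, values),
                delimiter=",")
            theirs = pdm.nj_tree()
            assert _splits(ours) == _splits_dendropy(theirs)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(labels=["A", "B"],
                                   values=np.array([[0.0, 1.0], [1.0, 0.0]])))


def _csv(labels, values):
    import io
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(str(v) for v in values[i]) + "\n")
    buf.seek(0)
    return buf


def _splits(tree):
    return tree.bipartitions()


def _splits_dendropy(tree):
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(taxa)
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


class TestBootstrap:
    def test_same_seed_reproduces_trees(self, default_family, params):
        from famkit import progressive_msa
        _, records, _ = default_family
        msa = progressive_msa(records[:5], params)
        t1 = bootstrap_trees(msa, 3, seed=9)
        t2 = bootstrap_trees(msa, 3, seed=9)
        assert [t.to_newick() for t in t1] == [t.to_newick() for t in t2]

    def test_unanimous_alignment_gives_unanimous_split(self):
        # every column supports AB|CD
        msa = aln({"A": "AAAA", "B": "AAAA", "C": "CCCC", "D": "CCCC"})
        trees = bootstrap_trees(msa, 20, seed=1)
        for t in trees:
            assert t.bipartitions() == {frozenset({"C", "D"})}

    def test_invalid_rep_count_rejected(self):
        msa = aln({"A": "AAAA", "B": "AAAA", "C": "CCCC"})
        with pytest.raises(PhyloError):
            bootstrap_trees(msa, 0, seed=1)


class TestConsensus:
    def test_identical_inputs_give_100_support(self):
        trees = [parse_newick("((A,B),(C,D),E);") for _ in range(4)]
        cons = majority_consensus(trees)
        assert cons.bipartitions() == trees[0].bipartitions()
        supports = [n.support for n in cons.walk()
                    if not n.is_leaf and n is not cons]
        assert supports and all(s == 100 for s in supports)

    def test_two_of_three_majority(self):
        trees = [parse_newick("((A,B),(C,D),E);"),
                 parse_newick("((A,B),(C,E),D);"),
                 parse_newick("((A,B),(C,D),E);")]
        cons = majority_consensus(trees)
        full = frozenset("ABCDE")
        split_support = {}
        for n in cons.walk():
            if n is cons or n.is_leaf:
                continue
            side = frozenset(n.leaf_names())
            if "A" in side:  # canonical orientation away from the anchor
                side = full - side
            split_support[tuple(sorted(side))] = n.support
        assert split_support.get(("C", "D", "E")) == 100  # the A,B|C,D,E split
        assert split_support.get(("C", "D")) == 67

    def test_matches_brute_force_bipartition_counts(self):
        rng = np.random.default_rng(7)
        labels = [f"t{k}" for k in range(6)]
        trees = []
        for _ in range(9):
            base = rng.uniform(0.1, 1.0, size=(6, 6))
            values = (base + base.T) / 2
            np.fill_diagonal(values, 0.0)
            trees.append(nj_tree(DistanceMatrix(labels=labels,
                                                values=values)))
        counts = Counter()
        for t in trees:
            counts.update(t.bipartitions())
        cons = majority_consensus(trees)
        majority = {s for s, c in counts.items() if 100 * c / 9 > 50}
        assert majority <= cons.bipartitions()
        for node in cons.walk():
            if node is cons or node.is_leaf or node.support is None:
                continue
            side = frozenset(node.leaf_names())
            full = frozenset(labels)
            if min(full) in side:
                side = full - side
            if side in counts:
                assert node.support == round(100 * counts[side] / 9)


class TestRooting:
    def test_outgroup_becomes_root_child(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_on_outgroup(t, "A")
        assert "A" in [c.label for c in rooted.children]
        assert rooted.bipartitions() <= t.bipartitions() | {frozenset()}

    def test_rerooting_is_idempotent(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        once = root_on_outgroup(t, "C")
        twice = root_on_outgroup(once, "C")
        assert once.to_newick() == twice.to_newick()

    def test_missing_label_rejected(self):
        with pytest.raises(PhyloError):
            root_on_outgroup(parse_newick("((A,B),C);"), "Z")
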