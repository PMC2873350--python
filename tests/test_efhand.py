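"""EF-hand annotation against calmodulin and the activity/cation rules."""

import itertools

import pytest

from famkit import (SeqRecord, annotate_and_classify, annotate_efhands,
                    classify_efhand, compare_efhands, detect_cterm_extension,
                    family_ef_table, measure_linker)
from famkit.efhand import (CANONICAL_EF1, CODE_DELETION, CODE_INSERTION,
                           CODE_POS1, CODE_POS12, EFHandAnnotation,
                           ReferenceLoops)
from famkit.errors import FamkitError

AA = "ACDEFGHIKLMNPQRSTVWY"


def loop_annotation(loop: str, insertions: int = 0) -> EFHandAnnotation:
    return EFHandAnnotation(ef_index=1, loop_gapped=loop,
                            insertions=insertions, query_start=1,
                            query_end=12 - loop.count("-"))


class TestAnnotate:
    def test_calmodulin_annotates_itself_exactly(self, calmodulin_ref, params):
        anns = annotate_efhands(calmodulin_ref.reference, calmodulin_ref,
                                params)
        assert anns[0].loop_gapped == CANONICAL_EF1
        for ann, (s, e) in zip(anns, calmodulin_ref.loops):
            assert (ann.query_start, ann.query_end) == (s, e)
            assert "-" not in ann.loop_gapped
            assert ann.insertions == 0

    def test_nterm_padding_shifts_coordinates_only(self, calmodulin_ref,
                                                   params):
        padded = SeqRecord(id="pad", residues="G" * 10 +
                           calmodulin_ref.reference.residues)
        anns = annotate_efhands(padded, calmodulin_ref, params)
        base = annotate_efhands(calmodulin_ref.reference, calmodulin_ref,
                                params)
        for a, b in zip(anns, base):
            assert a.loop_gapped == b.loop_gapped
            assert a.query_start == b.query_start + 10
            assert a.query_end == b.query_end + 10

    def test_loop_deletion_projected_as_gap_run(self, calmodulin_ref, params):
        res = calmodulin_ref.reference.residues
        s, _ = calmodulin_ref.loops[2]  # delete 3 residues inside EF3
        mutated = res[:s + 3] + res[s + 6:]
        anns = annotate_efhands(SeqRecord(id="del3", residues=mutated),
                                calmodulin_ref, params)
        assert anns[2].loop_gapped.count("-") == 3

    def test_short_query_rejected(self, calmodulin_ref, params):
        with pytest.raises(FamkitError):
            annotate_efhands(SeqRecord(id="tiny", residues="MKVEDKDGDG"),
                             calmodulin_ref, params)


class TestClassify:
    def test_canonical_loop_is_ca_specific(self):
        ann = classify_efhand(loop_annotation(CANONICAL_EF1))
        assert (ann.activity, ann.cation_class) == ("active", "Ca-specific")

    def test_e_to_d_swap_prefers_magnesium(self):
        ann = classify_efhand(loop_annotation("DKDGDGTITTKD"))
        assert (ann.activity, ann.cation_class) == ("active", "Mg-preferring")

    def test_deletion_inactivates_with_rationale(self):
        ann = classify_efhand(loop_annotation("DKDG---TTTKE"))
        assert ann.activity == "inactive"
        assert CODE_DELETION in ann.rationale
        assert ann.cation_class == "none"

    def test_insertion_inactivates(self):
        ann = classify_efhand(loop_annotation(CANONICAL_EF1, insertions=2))
        assert ann.activity == "inactive"
        assert CODE_INSERTION in ann.rationale

    def test_exhaustive_over_pos1_pos12_and_gap_count(self):
        """The classifier is a pure function of (pos1, pos12, gaps,
        insertions); sweep the whole space."""
        middle = CANONICAL_EF1[1:11]
        for pos1, pos12, gaps in itertools.product(AA, AA, (0, 1, 3)):
            core = pos1 + middle + pos12
            if gaps:
                core = core[:4] + "-" * gaps + core[4 + gaps:]
            ann = classify_efhand(loop_annotation(core))
            degraded = gaps > 0
            pos1_bad = pos1 not in "DNS"
            pos12_bad = pos12 not in "DE"
            if degraded or pos1_bad or pos12_bad:
                assert ann.activity == "inactive"
                assert (CODE_DELETION in ann.rationale) == degraded
                if not degraded:
                    assert (CODE_POS1 in ann.rationale) == pos1_bad
                    assert (CODE_POS12 in ann.rationale) == pos12_bad
            else:
                assert ann.activity == "active"
                assert ann.cation_class == (
                    "Ca-specific" if pos12 == "E" else "Mg-preferring")


class TestFamilyTableAndComparison:
    def test_all_calmodulin_table_is_uniformly_ca(self, calmodulin_ref,
                                                  params):
        anns = {f"cam{i}": annotate_and_classify(
            calmodulin_ref.reference, calmodulin_ref, params)
            for i in range(2)}
        table = family_ef_table(anns)
        assert (table.to_numpy() == "Ca").all()

    def test_identical_loops_conserved_100(self, calmodulin_ref, params):
        a = annotate_and_classify(calmodulin_ref.reference, calmodulin_ref,
                                  params)
        comps = compare_efhands(a, a)
        assert all(c.conserved_pct == 100.0 for c in comps)
        assert all(c.pos12_a == c.pos12_b for c in comps)


class TestStructuralFeatures:
    def test_no_extension_on_reference_itself(self, calmodulin_ref, params):
        assert detect_cterm_extension(calmodulin_ref.reference,
                                      calmodulin_ref, params) == 0

    def test_appended_tail_counted_exactly(self, calmodulin_ref, params):
        tail = "LVAALVAALVAALVAALVAA"  # 20 hydrophobic residues
        rec = SeqRecord(id="ext",
                        residues=calmodulin_ref.reference.residues + tail)
        assert detect_cterm_extension(rec, calmodulin_ref, params) == 20

    def test_reference_linker_length(self, calmodulin_ref, params):
        assert measure_linker(calmodulin_ref.reference, calmodulin_ref,
                              params) == calmodulin_ref.linker_length

    def test_linker_insertion_adds_exactly(self, calmodulin_ref, params):
        res = calmodulin_ref.reference.residues
        mid = calmodulin_ref.loops[1][1] + 12  # inside the EF2-EF3 linker
        stuffed = res[:mid] + "PGAPGAPGAPGAPGA" + res[mid:]  # +15
        rec = SeqRecord(id="stuffed", residues=stuffed)
        assert measure_linker(rec, calmodulin_ref, params) == \
            calmodulin_ref.linker_length + 15
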