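"""Element definitions, strand matching and the orientation grammar."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import oracle_occurrences, oracle_revcomp
from smadscan.errors import InputError
from smadscan.grammar import (
    CANONICAL_ELEMENTS,
    BindingElement,
    BindingMode,
    Responsiveness,
    Strand,
    classify_binding_modes,
    element_occurrences,
    is_palindromic,
    make_composite_hit,
    predict_responsiveness,
    reverse_complement,
)
from smadscan.scanner import scan_composites

iupac_strings = st.text(alphabet="ACGTRYSWKMBDHVN", max_size=40)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GTCTG", "CAGAC"),  # sense SBE -> antisense form
            ("GGCGCC", "GGCGCC"),  # palindrome maps to itself
            ("", ""),
            ("RYSWKM", "KMWSRY"),
        ],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(iupac_strings)
    @settings(max_examples=200, derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    @given(st.text(alphabet="ACGT", max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_independent_complement_table(self, seq):
        assert reverse_complement(seq) == oracle_revcomp(seq)

    def test_rejects_non_iupac_naming_position(self):
        with pytest.raises(InputError, match="position 2"):
            reverse_complement("GGXGG")


class TestElements:
    @pytest.mark.parametrize(
        "eid,palindromic",
        [("pGC_SBE", True), ("pSBE", True), ("SBE", False),
         ("npGC_SBE", False), ("FIVE_GC", False)],
    )
    def test_palindromicity(self, eid, palindromic):
        assert is_palindromic(CANONICAL_ELEMENTS[eid]) is palindromic

    def test_degenerate_expansion(self):
        assert set(CANONICAL_ELEMENTS["FIVE_GC"].variants) == {"GGCGC", "GGCCG"}

    def test_minimum_length_enforced(self):
        with pytest.raises(InputError):
            BindingElement("tiny", "GTC")

    def test_user_elements_accept_seven_mer_gc_palindrome_variant(self):
        # the 7-bp written form of the GC palindrome is a legal user element
        el = BindingElement("pGC_SBE_7", "GGCGCCC")
        assert el.length == 7 and not is_palindromic(el)


class TestOccurrences:
    def test_antisense_sbe(self):
        (inst,) = element_occurrences("CAGAC", CANONICAL_ELEMENTS["SBE"])
        assert (inst.start, inst.end) == (0, 5)
        assert inst.strands == frozenset({Strand.MINUS})

    def test_palindrome_reported_once_with_both_strands(self):
        (inst,) = element_occurrences("GGCGCC", CANONICAL_ELEMENTS["pGC_SBE"])
        assert inst.strands_label == "both"

    def test_overlapping_instances_all_reported(self):
        # GTCTGTCTG carries two overlapping sense SBE copies
        occ = element_occurrences("GTCTGTCTG", CANONICAL_ELEMENTS["SBE"])
        assert [o.start for o in occ] == [0, 4]

    def test_soft_masked_and_n_bases_never_match(self):
        assert element_occurrences("ggcgcc", CANONICAL_ELEMENTS["pGC_SBE"]) == []
        assert element_occurrences("GGCGNC", CANONICAL_ELEMENTS["pGC_SBE"]) == []

    def test_matches_brute_force_on_random_sequences(self, rng):
        from conftest import random_dna

        for _ in range(25):
            seq = random_dna(rng, 1000)
            for el in CANONICAL_ELEMENTS.values():
                got = {
                    o.start: frozenset(s.value for s in o.strands)
                    for o in element_occurrences(seq, el)
                }
                assert got == oracle_occurrences(seq, el.variants)


class TestBindingModes:
    @pytest.mark.parametrize(
        "up,down,expected",
        [
            ({"both"}, {"plus"}, {"face_to_back", "back_to_back"}),
            ({"both"}, {"minus"}, {"face_to_face", "face_to_back"}),
            ({"plus"}, {"plus"}, {"face_to_back"}),
            ({"minus"}, {"plus"}, {"back_to_back"}),
            ({"both"}, {"both"},
             {"face_to_face", "face_to_back", "back_to_back"}),
        ],
    )
    def test_mode_table(self, up, down, expected):
        assert {m.value for m in classify_binding_modes(up, down)} == expected

    def test_empty_strand_set_rejected(self):
        with pytest.raises(InputError):
            classify_binding_modes(set(), {"plus"})

    def test_locus_reverse_complement_preserves_mode_set(self, rng):
        # flipping the whole locus swaps the elements and their strands
        flip = {Strand.PLUS: Strand.MINUS, Strand.MINUS: Strand.PLUS}
        strand_sets = [
            frozenset({Strand.PLUS}),
            frozenset({Strand.MINUS}),
            frozenset({Strand.PLUS, Strand.MINUS}),
        ]
        for up in strand_sets:
            for down in strand_sets:
                direct = classify_binding_modes(up, down)
                flipped = classify_binding_modes(
                    frozenset(flip[s] for s in down),
                    frozenset(flip[s] for s in up),
                )
                assert direct == flipped


def _hit(seq, element_a, element_b, spacer=5):
    hits = scan_composites(
        seq, CANONICAL_ELEMENTS[element_a], CANONICAL_ELEMENTS[element_b], spacer
    )
    assert len(hits) >= 1
    return hits[0]


class TestResponsiveness:
    def test_id_like_sense_is_bmp_responsive(self):
        h = _hit("GGCGCCAACTTGTCTG", "pGC_SBE", "SBE")
        assert h.label is Responsiveness.BMP

    @pytest.mark.parametrize("spacer,linker", [(4, "AACT"), (6, "AACTTT")])
    def test_one_bp_linker_change_abolishes_response(self, spacer, linker):
        h = _hit(f"GGCGCC{linker}GGCGCC", "pGC_SBE", "pGC_SBE", spacer)
        assert h.label is Responsiveness.NONE

    def test_npgc_homocomposite_nonresponsive(self):
        h = _hit("GGCTCCAACTTGGCTCC", "npGC_SBE", "npGC_SBE")
        assert h.label is Responsiveness.NONE

    def test_psbe_pair_is_tgfb_responsive(self):
        h = _hit("GTCTAGACAACTTGTCTAGAC", "pSBE", "pSBE")
        assert h.label is Responsiveness.TGFB

    def test_full_antisense_heterocomposite_is_weakly_responsive(self):
        h = _hit("CAGACAACTTGGCGCC", "pGC_SBE", "SBE")
        assert h.label is Responsiveness.BMP_WEAK

    def test_sbe_antisense_heterocomposite_loses_back_to_back(self):
        h = _hit("GGCGCCAACTTCAGAC", "pGC_SBE", "SBE")
        assert BindingMode.BACK_TO_BACK not in h.modes
        assert h.label is Responsiveness.NONE

    def test_unknown_element_id_rejected_in_strict_mode(self):
        h = _hit("GGCGCCAACTTGTCTG", "pGC_SBE", "SBE")
        from dataclasses import replace

        bogus = replace(h, upstream=replace(h.upstream, element_id="mystery"))
        with pytest.raises(InputError):
            predict_responsiveness(bogus)
        assert predict_responsiveness(bogus, strict=False) is Responsiveness.NONE

    @pytest.mark.parametrize("spacer_len", list(range(0, 31)))
    def test_bmp_label_requires_exactly_five_bp(self, spacer_len):
        """No canonical pair at any other spacing is ever BMP-labelled."""
        ids = list(CANONICAL_ELEMENTS)
        spacer = "AT" * 16
        for a in ids:
            for b in ids:
                seq_a = CANONICAL_ELEMENTS[a].variants[0]
                seq_b = CANONICAL_ELEMENTS[b].variants[0]
                seq = seq_a + spacer[:spacer_len] + seq_b
                hits = scan_composites(
                    seq, CANONICAL_ELEMENTS[a], CANONICAL_ELEMENTS[b], spacer_len
                )
                for h in hits:
                    if spacer_len != 5:
                        assert h.label not in (
                            Responsiveness.BMP,
                            Responsiveness.BMP_WEAK,
                            Responsiveness.TGFB,
                        )

    def test_single_substitution_variants_lose_bmp_status(self):
        """Any point permutation of the GC palindrome leaves the whitelist."""
        pgc = "GGCGCC"
        for pos in range(6):
            for base in "ACGT":
                if base == pgc[pos]:
                    continue
                variant = pgc[:pos] + base + pgc[pos + 1 :]
                seq = variant + "AACTT" + "GTCTG"
                hits = scan_composites(
                    seq, CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
                )
                assert all(
                    h.label not in (Responsiveness.BMP, Responsiveness.BMP_WEAK)
                    for h in hits
                )

    def test_composite_hit_rejects_overlapping_elements(self):
        from smadscan.grammar import ElementInstance, CompositeHit

        up = ElementInstance("pGC_SBE", 0, 6, frozenset({Strand.PLUS}))
        down = ElementInstance("pGC_SBE", 4, 10, frozenset({Strand.PLUS}))
        with pytest.raises(InputError):
            CompositeHit(up, down, "", -2, frozenset({BindingMode.FACE_TO_BACK}),
                         Responsiveness.NONE)
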