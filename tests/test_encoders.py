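"""Slot-template encodings for phonology and orthography."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilexmap.encoders import (
    ORTH_TEMPLATE,
    PHON_TEMPLATE,
    TemplateOverflowError,
    UnknownSymbolError,
    assign_slots,
    encode_orthography,
    encode_phonology,
    letter_vector_from_glyph,
)

B_VECTOR = [0.23, 0.23, 0.08, 0.26, 0.12, 0.22, 0.01, 0.18, 0.01]
D_VECTOR = [0.01, 0.17, 0.00, 0.23, 0.13, 0.22, 0.23, 0.23, 0.08]


class TestPhonology:
    def test_empty_word_is_all_zero(self, phoneme_table):
        vec = encode_phonology((), phoneme_table)
        assert vec.shape == (81,)
        assert not vec.any()

    def test_any_legal_word_has_length_81(self, phoneme_table):
        for word in ("pa", "fles", "bidon", "tra"):
            assert encode_phonology(phoneme_table.parse(word), phoneme_table).shape == (81,)

    def test_cv_word_fills_first_c_and_v_slots(self, phoneme_table):
        """A single CV syllable lights exactly 6 coordinates: group-1 C1 + V1."""
        vec = encode_phonology(("p", "a"), phoneme_table)
        nz = np.nonzero(vec)[0]
        assert len(nz) == 6
        # group 1 has C slots 0-1 and V slots 2-3; each slot spans 3 coords
        assert set(nz) == {0, 1, 2, 6, 7, 8}

    def test_unknown_phoneme_names_the_symbol(self, phoneme_table):
        with pytest.raises(UnknownSymbolError, match="q"):
            encode_phonology(("q",), phoneme_table)

    def test_consonant_run_overflow(self, phoneme_table):
        # four consonants exceed every 3-slot C block
        with pytest.raises(TemplateOverflowError):
            encode_phonology(("p", "s", "t", "r", "a"), phoneme_table)

    def test_too_many_alternations_overflow(self, phoneme_table):
        word = ("p", "a") * 7  # seven CV groups > six template groups
        with pytest.raises(TemplateOverflowError):
            encode_phonology(word, phoneme_table)

    def test_deterministic(self, phoneme_table):
        w = phoneme_table.parse("fles")
        a = encode_phonology(w, phoneme_table)
        b = encode_phonology(w, phoneme_table)
        assert np.array_equal(a, b)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(st.sampled_from("ptkbdfsmnlr"), st.sampled_from("aeiou")),
        min_size=1, max_size=5,
    ))
    def test_zero_padding_counts_filled_slots(self, syllables):
        """The number of nonzero 3-d slot blocks equals the phoneme count."""
        from bilexmap.encoders import PhonemeTable

        table = PhonemeTable.load()
        word = tuple(p for pair in syllables for p in pair)
        vec = encode_phonology(word, table).reshape(27, 3)
        assert int((vec != 0).any(axis=1).sum()) == len(word)


class TestOrthography:
    def test_empty_word_is_all_zero(self, letter_table):
        vec = encode_orthography((), letter_table)
        assert vec.shape == (297,)
        assert not vec.any()

    def test_bidon_layout(self, letter_table):
        """b/i open group 1, d/o group 2, n group 3; everything else zero."""
        vec = encode_orthography(letter_table.parse("bidon"), letter_table)
        slots = vec.reshape(33, 9)
        # group g occupies slots 6g..6g+2 (C) and 6g+3..6g+5 (V)
        expected = {0: "b", 3: "i", 6: "d", 9: "o", 12: "n"}
        for slot, letter in expected.items():
            assert np.array_equal(slots[slot], letter_table.vector(letter))
        filled = set(np.nonzero((slots != 0).any(axis=1))[0])
        assert filled == set(expected)

    def test_packaged_b_and_d_vectors(self, letter_table):
        assert np.allclose(letter_table.vector("b"), B_VECTOR)
        assert np.allclose(letter_table.vector("d"), D_VECTOR)
        vec = encode_orthography(letter_table.parse("bidon"), letter_table)
        assert np.allclose(vec[:9], B_VECTOR)

    def test_unknown_letter(self, letter_table):
        with pytest.raises(UnknownSymbolError):
            letter_table.parse("naïve")  # ï is not in the inventory

    def test_multiword_names_concatenate(self, letter_table):
        assert letter_table.parse("pot de lait") == tuple("potdelait")

    def test_accented_letters_covered(self, letter_table):
        for ch in ("è", "é", "î"):
            assert ch in letter_table
            assert letter_table.is_vowel(ch)


class TestRunFilling:
    def test_vowel_initial_word_starts_in_group_one_v_block(self, letter_table):
        pairs = assign_slots(tuple("ab"), letter_table.is_vowel, ORTH_TEMPLATE)
        assert pairs == [("a", 3), ("b", 6)]

    def test_phonological_template_capacity(self):
        assert sum(c + v for c, v in PHON_TEMPLATE) == 27
        assert sum(c + v for c, v in ORTH_TEMPLATE) == 33


class TestGlyphVector:
    def test_all_white_gives_zeros(self):
        assert np.array_equal(letter_vector_from_glyph(np.zeros((90, 90))), np.zeros(9))

    def test_all_black_gives_ones(self):
        assert np.array_equal(letter_vector_from_glyph(np.ones((90, 90))), np.ones(9))

    def test_single_cell_black(self):
        bm = np.zeros((90, 90))
        bm[:30, :30] = 1
        assert np.array_equal(letter_vector_from_glyph(bm),
                              [1, 0, 0, 0, 0, 0, 0, 0, 0])

    def test_matches_brute_force_cell_counts(self, rng):
        bm = (rng.random((90, 90)) < 0.3).astype(int)
        expected = [
            bm[30 * r: 30 * r + 30, 30 * c: 30 * c + 30].sum() / 900.0
            for r in range(3) for c in range(3)
        ]
        assert np.allclose(letter_vector_from_glyph(bm), expected)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            letter_vector_from_glyph(np.zeros((60, 90)))
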