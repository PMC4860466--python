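"""Fixed-length input encodings for the three feature maps.

Semantic input is already vectorial (per-feature rater proportions in [0, 1]),
so this module concerns the two word-form codes:

* phonology — each phoneme is a 3-d articulatory coordinate (consonant/vowel
  flag, place of articulation / backness, manner / height) and a word is
  left-justified into a five-syllable slot template ``CCVV/CCCVV/CCCVV/CCCVV/
  CCCVV/CCC`` (27 slots), giving an 81-d vector;
* orthography — each letter is a 9-d vector of black-pixel proportions over a
  3x3 partition of its 90x90 glyph, and a word is laid into the template
  ``CCCVVV/CCCVVV/CCCVVV/CCCVVV/CCCVVV/CCC`` (33 slots), giving a 297-d vector.

Both templates are filled by the same rule: the word is parsed into maximal
consonant/vowel runs; a run occupies the C- or V-block of the current group,
left-justified, and a consonant run that follows a vowel run opens the next
group.  Unfilled slots stay exactly zero.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EncodingError",
    "UnknownSymbolError",
    "TemplateOverflowError",
    "PhonemeTable",
    "LetterTable",
    "Lexeme",
    "PHON_TEMPLATE",
    "ORTH_TEMPLATE",
    "encode_phonology",
    "encode_orthography",
    "letter_vector_from_glyph",
    "load_lexicon",
]


class EncodingError(ValueError):
    """Base class for encoding failures."""


class UnknownSymbolError(EncodingError):
    """A phoneme or letter is absent from the coordinate table."""

    def __init__(self, symbol: str, kind: str = "symbol"):
        self.symbol = symbol
        super().__init__(f"unknown {kind}: {symbol!r}")


class TemplateOverflowError(EncodingError):
    """The word does not fit the slot template."""


# Templates as (n_consonant_slots, n_vowel_slots) per group; the trailing
# (k, 0) group holds word-final consonant clusters.
PHON_TEMPLATE: tuple[tuple[int, int], ...] = (
    (2, 2), (3, 2), (3, 2), (3, 2), (3, 2), (3, 0),
)
ORTH_TEMPLATE: tuple[tuple[int, int], ...] = (
    (3, 3), (3, 3), (3, 3), (3, 3), (3, 3), (3, 0),
)


def _template_slots(template: Sequence[tuple[int, int]]) -> int:
    return sum(c + v for c, v in template)


def _runs(symbols: Sequence[str], is_vowel) -> list[tuple[bool, list[str]]]:
    """Split into maximal runs, tagged True for vowel runs."""
    runs: list[tuple[bool, list[str]]] = []
    for s in symbols:
        v = bool(is_vowel(s))
        if runs and runs[-1][0] == v:
            runs[-1][1].append(s)
        else:
            runs.append((v, [s]))
    return runs


def assign_slots(
    symbols: Sequence[str],
    is_vowel,
    template: Sequence[tuple[int, int]] = PHON_TEMPLATE,
) -> list[tuple[str, int]]:
    """Map each symbol to a global slot index under the run-filling rule.

    Slots are numbered group by group, consonant block before vowel block.
    Raises :class:`TemplateOverflowError` when a run exceeds its block or the
    word has more consonant/vowel alternations than the template has groups.
    """
    starts = []  # (c_start, v_start) per group
    pos = 0
    for n_c, n_v in template:
        starts.append((pos, pos + n_c))
        pos += n_c + n_v

    out: list[tuple[str, int]] = []
    group = 0
    prev_was_vowel: bool | None = None
    for is_v, run in _runs(symbols, is_vowel):
        if prev_was_vowel is not None and not is_v:
            group += 1  # a consonant run after a vowel run opens a new group
        if group >= len(template):
            raise TemplateOverflowError(
                f"word {''.join(symbols)!r} has more consonant/vowel "
                f"alternations than the template has groups"
            )
        n_c, n_v = template[group]
        block = n_v if is_v else n_c
        if len(run) > block:
            kind = "vowel" if is_v else "consonant"
            raise TemplateOverflowError(
                f"{kind} run {''.join(run)!r} of length {len(run)} exceeds "
                f"the {block}-slot block of group {group + 1}"
            )
        base = starts[group][1] if is_v else starts[group][0]
        out.extend((s, base + i) for i, s in enumerate(run))
        prev_was_vowel = is_v
    return out


@dataclass(frozen=True)
class PhonemeTable:
    """IPA symbol -> 3-d articulatory coordinate, with a C/V tag per symbol.

    Coordinates live in [0, 1] and are scaled away from zero so that a filled
    slot is never the all-zero padding pattern.
    """

    coords: Mapping[str, np.ndarray]
    vowels: frozenset[str]

    def __post_init__(self):
        for sym, vec in self.coords.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (3,):
                raise ValueError(f"phoneme {sym!r} must have 3 coordinates")
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"phoneme {sym!r} coordinates outside [0, 1]")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.coords

    def is_vowel(self, symbol: str) -> bool:
        return symbol in self.vowels

    def vector(self, symbol: str) -> np.ndarray:
        try:
            return np.asarray(self.coords[symbol], dtype=float)
        except KeyError:
            raise UnknownSymbolError(symbol, "phoneme") from None

    def parse(self, ipa: str) -> tuple[str, ...]:
        """Greedy longest-match segmentation of an IPA string.

        Whitespace separates phonemes explicitly; otherwise the longest known
        symbol is consumed at each position (handles combining diacritics).
        """
        s = unicodedata.normalize("NFC", ipa)
        maxlen = max((len(k) for k in self.coords), default=1)
        phonemes: list[str] = []
        i = 0
        while i < len(s):
            if s[i].isspace():
                i += 1
                continue
            for L in range(min(maxlen, len(s) - i), 0, -1):
                if s[i : i + L] in self.coords:
                    phonemes.append(s[i : i + L])
                    i += L
                    break
            else:
                raise UnknownSymbolError(s[i], "phoneme")
        return tuple(phonemes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhonemeTable":
        coords = {}
        vowels = set()
        for _, row in df.iterrows():
            sym = unicodedata.normalize("NFC", str(row["symbol"]))
            coords[sym] = np.array(
                [row["cv"], row["place"], row["manner"]], dtype=float
            )
            if str(row["kind"]).upper() == "V":
                vowels.add(sym)
        return cls(coords=coords, vowels=frozenset(vowels))

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PhonemeTable":
        """Load the packaged table (Dutch + French inventories) or a CSV."""
        if path is None:
            with resources.files("bilexmap.data").joinpath("phonemes.csv").open() as fh:
                df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
        return cls.from_frame(df)


DEFAULT_VOWEL_LETTERS = frozenset("aeiouyèéî")  # a e i o u y è é î


@dataclass(frozen=True)
class LetterTable:
    """Grapheme -> 9-d black-pixel-proportion vector.

    Covers the 26 base letters plus è, é, î.  Which letters count as vowels
    for template filling is configurable (the default set is
    {a, e, i, o, u, y, è, é, î}).
    """

    coords: Mapping[str, np.ndarray]
    vowels: frozenset[str] = field(default=DEFAULT_VOWEL_LETTERS)

    def __post_init__(self):
        for sym, vec in self.coords.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (9,):
                raise ValueError(f"letter {sym!r} must have 9 coordinates")
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"letter {sym!r} coordinates outside [0, 1]")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.coords

    def is_vowel(self, symbol: str) -> bool:
        return symbol in self.vowels

    def vector(self, symbol: str) -> np.ndarray:
        try:
            return np.asarray(self.coords[symbol], dtype=float)
        except KeyError:
            raise UnknownSymbolError(symbol, "letter") from None

    def parse(self, spelling: str) -> tuple[str, ...]:
        """One letter per character, case-folded; spaces and hyphens dropped.

        Multi-word names are encoded as a single concatenated form.
        """
        s = unicodedata.normalize("NFC", spelling).lower()
        letters = []
        for ch in s:
            if ch in " -'":
                continue
            if ch not in self.coords:
                raise UnknownSymbolError(ch, "letter")
            letters.append(ch)
        return tuple(letters)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, vowels: Iterable[str] | None = None) -> "LetterTable":
        cols = [f"p{i}" for i in range(1, 10)]
        coords = {
            unicodedata.normalize("NFC", str(row["letter"])): row[cols].to_numpy(dtype=float)
            for _, row in df.iterrows()
        }
        vset = DEFAULT_VOWEL_LETTERS if vowels is None else frozenset(vowels)
        return cls(coords=coords, vowels=vset)

    @classmethod
    def load(cls, path: str | Path | None = None, vowels: Iterable[str] | None = None) -> "LetterTable":
        if path is None:
            with resources.files("bilexmap.data").joinpath("letters.csv").open() as fh:
                df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
        return cls.from_frame(df, vowels=vowels)


def encode_phonology(phonemes: Sequence[str], table: PhonemeTable) -> np.ndarray:
    """Encode a phoneme sequence into the 81-d slot vector (27 slots x 3)."""
    n_slots = _template_slots(PHON_TEMPLATE)
    vec = np.zeros(n_slots * 3)
    for sym, slot in assign_slots(phonemes, table.is_vowel, PHON_TEMPLATE):
        vec[slot * 3 : slot * 3 + 3] = table.vector(sym)
    return vec


def encode_orthography(graphemes: Sequence[str], table: LetterTable) -> np.ndarray:
    """Encode a letter sequence into the 297-d slot vector (33 slots x 9)."""
    n_slots = _template_slots(ORTH_TEMPLATE)
    vec = np.zeros(n_slots * 9)
    for sym, slot in assign_slots(graphemes, table.is_vowel, ORTH_TEMPLATE):
        vec[slot * 9 : slot * 9 + 9] = table.vector(sym)
    return vec


def letter_vector_from_glyph(bitmap: np.ndarray) -> np.ndarray:
    """9-d vector of black-pixel proportions over a 3x3 partition.

    ``bitmap`` is a 90x90 binary image (nonzero = black).  Each of the nine
    30x30 cells contributes its black count divided by the 900 pixels of the
    cell, in row-major cell order.
    """
    bm = np.asarray(bitmap)
    if bm.shape != (90, 90):
        raise ValueError(f"glyph bitmap must be 90x90, got {bm.shape}")
    black = (bm != 0).astype(float)
    cells = black.reshape(3, 30, 3, 30).sum(axis=(1, 3))
    return (cells / 900.0).ravel()


@dataclass(frozen=True)
class Lexeme:
    """One word form with its derived slot encodings."""

    word_id: str
    language: str
    phonemes: tuple[str, ...]
    graphemes: tuple[str, ...]
    phon_vec: np.ndarray
    orth_vec: np.ndarray

    @classmethod
    def build(
        cls,
        word_id: str,
        language: str,
        ipa: str,
        spelling: str,
        phoneme_table: PhonemeTable,
        letter_table: LetterTable,
    ) -> "Lexeme":
        phonemes = phoneme_table.parse(ipa)
        graphemes = letter_table.parse(spelling)
        return cls(
            word_id=word_id,
            language=language,
            phonemes=phonemes,
            graphemes=graphemes,
            phon_vec=encode_phonology(phonemes, phoneme_table),
            orth_vec=encode_orthography(graphemes, letter_table),
        )


def load_lexicon(
    source: str | Path | pd.DataFrame,
    phoneme_table: PhonemeTable,
    letter_table: LetterTable,
) -> list[Lexeme]:
    """Read a lexicon table (columns word, language, ipa, spelling) into Lexemes."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"word", "language", "ipa", "spelling"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lexicon table missing columns: {sorted(missing)}")
    return [
        Lexeme.build(
            str(row.word), str(row.language), str(row.ipa), str(row.spelling),
            phoneme_table, letter_table,
        )
        for row in df.itertuples()
    ]
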