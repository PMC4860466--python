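"""Encode word forms into the slot-template vectors the maps consume.

Shows the 81-d phonological code (27 slots x 3 articulatory dims) and the
297-d orthographic code (33 slots x 9 glyph-pixel dims) for a small word,
and how the template assigns letters to consonant/vowel slot groups.
"""

import numpy as np

from bilexmap import LetterTable, PhonemeTable, encode_orthography, encode_phonology

phonemes = PhonemeTable.load()
letters = LetterTable.load()

word = "bidon"
phon = encode_phonology(phonemes.parse(word), phonemes)
orth = encode_orthography(letters.parse(word), letters)

print(f"word: {word}")
print(f"phonological vector: length {phon.size}, "
      f"{int((phon.reshape(27, 3) != 0).any(axis=1).sum())} slots filled")
print(f"orthographic vector: length {orth.size}, "
      f"{int((orth.reshape(33, 9) != 0).any(axis=1).sum())} slots filled")

slots = orth.reshape(33, 9)
filled = np.nonzero((slots != 0).any(axis=1))[0]
print("filled orthographic slots (group, position):",
      [(int(s) // 6 + 1, int(s) % 6 + 1) for s in filled])
print("letter-b slot vector:", np.round(slots[0], 2))
# Each filled slot carries one letter's 9-d black-pixel-proportion vector;
# the alternating consonant/vowel runs of 'bidon' occupy groups 1-3.
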