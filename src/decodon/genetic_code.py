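"""Alphabets, the standard genetic code, and exact translation.

The code is the many-to-one map from the 64 RNA codons (trigrams over
``{A, U, C, G}``) onto the 20 single-letter amino-acid symbols plus the stop
mark ``*``.  It is the ground truth both for synthesising protein targets and
for judging whether a trained decoder has recovered the full table.

Two fixed orderings are used throughout the package:

* **Codon order** — lexicographic over the alphabetical nucleotide order
  ``A < C < G < U``, so ``AAA`` has index 0 and ``UUU`` index 63.
* **Class order** — the 20 amino-acid letters alphabetically, followed by
  ``*`` at index 20.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List

RNA_ALPHABET = "ACGU"

#: All 64 codons in canonical (lexicographic A<C<G<U) order.
CODONS: List[str] = ["".join(p) for p in product(RNA_ALPHABET, repeat=3)]

#: Codon string -> canonical index in [0, 64).
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: The 21 target classes: 20 amino acids alphabetically, stop mark last.
AMINO_ACIDS: List[str] = sorted("ACDEFGHIKLMNPQRSTVWY") + ["*"]

#: Class symbol -> canonical index in [0, 21).
AA_INDEX: Dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

STOP_SYMBOL = "*"
START_CODON = "AUG"
STOP_CODONS = ("UAA", "UAG", "UGA")

# Standard genetic code, written per amino acid for readability.
_CODE_BY_AA = {
    "A": ("GCU", "GCC", "GCA", "GCG"),
    "C": ("UGU", "UGC"),
    "D": ("GAU", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("UUU", "UUC"),
    "G": ("GGU", "GGC", "GGA", "GGG"),
    "H": ("CAU", "CAC"),
    "I": ("AUU", "AUC", "AUA"),
    "K": ("AAA", "AAG"),
    "L": ("UUA", "UUG", "CUU", "CUC", "CUA", "CUG"),
    "M": ("AUG",),
    "N": ("AAU", "AAC"),
    "P": ("CCU", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGU", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("UCU", "UCC", "UCA", "UCG", "AGU", "AGC"),
    "T": ("ACU", "ACC", "ACA", "ACG"),
    "V": ("GUU", "GUC", "GUA", "GUG"),
    "W": ("UGG",),
    "Y": ("UAU", "UAC"),
    "*": STOP_CODONS,
}

_STANDARD_CODE: Dict[str, str] = {
    codon: aa for aa, codons in _CODE_BY_AA.items() for codon in codons
}


class InvalidAlphabetError(ValueError):
    """A character outside the expected nucleotide alphabet was seen."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid nucleotide {char!r} at position {position} "
            f"(expected one of A, C, G, T, U in either case)"
        )


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


def standard_code() -> Dict[str, str]:
    """Return the standard genetic code as a codon -> symbol dict.

    The returned mapping has exactly 64 entries whose image is the full
    21-symbol class alphabet; the three stop codons map to ``*``.  A fresh
    copy is returned on each call so callers may mutate it freely (e.g. to
    build deliberately corrupted reference tables in tests).
    """
    return dict(_STANDARD_CODE)


def normalize_sequence(raw: str) -> str:
    """Normalise a DNA or RNA string to uppercase RNA (``T`` -> ``U``).

    Parameters
    ----------
    raw : str
        Nucleotide sequence over ``{A, C, G, T, U}`` in either case.

    Raises
    ------
    InvalidAlphabetError
        If any other character occurs; the error names the 1-based
        offending position.
    """
    up = raw.upper()
    for pos, ch in enumerate(up, start=1):
        if ch not in "ACGTU":
            raise InvalidAlphabetError(raw[pos - 1], pos)
    return up.replace("T", "U")


def translate(orf: str, code: Dict[str, str] | None = None) -> str:
    """Translate a frame-aligned RNA string codon by codon.

    Every non-overlapping triplet is looked up in ``code`` (the standard
    code by default); stop codons yield ``*`` rather than terminating, so
    the output length is always ``len(orf) // 3``.

    Raises
    ------
    FrameError
        If ``len(orf)`` is not divisible by 3.
    InvalidAlphabetError
        If a triplet is not a valid RNA codon.
    """
    if len(orf) % 3 != 0:
        raise FrameError(
            f"sequence length {len(orf)} is not a multiple of 3"
        )
    if code is None:
        code = _STANDARD_CODE
    out = []
    for i in range(0, len(orf), 3):
        codon = orf[i : i + 3]
        try:
            out.append(code[codon])
        except KeyError:
            for j, ch in enumerate(codon):
                if ch not in RNA_ALPHABET:
                    raise InvalidAlphabetError(ch, i + j + 1) from None
            raise
    return "".join(out)


def codons_to_indices(rna: str) -> List[int]:
    """Map a frame-aligned RNA string to canonical codon indices."""
    if len(rna) % 3 != 0:
        raise FrameError(f"sequence length {len(rna)} is not a multiple of 3")
    return [CODON_INDEX[rna[i : i + 3]] for i in range(0, len(rna), 3)]
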