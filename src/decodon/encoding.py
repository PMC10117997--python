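"""Numeric representations of codons and amino-acid classes.

Three fixed input encodings are supported:

* ``OHE64`` — one 64-bit one-hot vector per codon (codon-level vocabulary);
* ``OHE12`` — concatenation of three 4-bit nucleotide one-hots (3 x 4 bits);
* ``NUC4-SEQ3`` — the same three 4-bit nucleotide vectors kept as a
  3-timestep sequence for recurrent readers.

Targets are always 21-bit one-hots.  The nucleotide basis order is
``(A, U, C, G)`` — note this deliberately differs from the alphabetical
``A < C < G < U`` order used for codon indexing; the two conventions are
independent and both fixed.

Learnable dense codon embeddings (``EmbeddingSpec``) generalise one-hot
input: 64 rows of dimensionality ``d``, trained jointly with the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genetic_code import AA_INDEX, AMINO_ACIDS, CODON_INDEX, CODONS

#: Nucleotide one-hot basis order (A, U, C, G).
NUC_ORDER = "AUCG"
_NUC_POS = {n: i for i, n in enumerate(NUC_ORDER)}

VALID_SCHEMES = ("OHE64", "OHE12", "NUC4-SEQ3")


@dataclass(frozen=True)
class EncodingScheme:
    """A named fixed input encoding with its per-codon width."""

    name: str

    def __post_init__(self):
        if self.name not in VALID_SCHEMES:
            raise ValueError(
                f"unknown encoding scheme {self.name!r}; expected one of {VALID_SCHEMES}"
            )

    @property
    def width(self) -> int:
        """Flat input width per codon (12 for the sequence scheme: 3 x 4)."""
        return {"OHE64": 64, "OHE12": 12, "NUC4-SEQ3": 12}[self.name]

    @property
    def is_sequence(self) -> bool:
        return self.name == "NUC4-SEQ3"


def ohe_nucleotide(n: str) -> np.ndarray:
    """One-hot encode a single nucleotide on the (A, U, C, G) basis."""
    if n not in _NUC_POS:
        raise ValueError(f"invalid nucleotide {n!r}; expected one of A, U, C, G")
    v = np.zeros(4)
    v[_NUC_POS[n]] = 1.0
    return v


def encode_codon(codon: str, scheme: EncodingScheme) -> np.ndarray:
    """Encode one codon under the given scheme.

    Returns a 64-vector (OHE64), a 12-vector (OHE12), or a 3x4 matrix of
    per-nucleotide timesteps (NUC4-SEQ3).
    """
    if codon not in CODON_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    if scheme.name == "OHE64":
        v = np.zeros(64)
        v[CODON_INDEX[codon]] = 1.0
        return v
    nucs = np.stack([ohe_nucleotide(n) for n in codon])
    return nucs if scheme.is_sequence else nucs.reshape(12)


def encode_amino_acid(symbol: str) -> np.ndarray:
    """21-bit one-hot of an amino-acid symbol ('*' at index 20)."""
    if symbol not in AA_INDEX:
        raise ValueError(f"invalid amino-acid symbol {symbol!r}")
    v = np.zeros(21)
    v[AA_INDEX[symbol]] = 1.0
    return v


# Precomputed lookup tables, indexed by canonical codon index.  Training
# batches are encoded by fancy-indexing these rather than re-encoding
# strings pair by pair.
OHE64_TABLE = np.eye(64)
OHE12_TABLE = np.stack(
    [encode_codon(c, EncodingScheme("OHE12")) for c in CODONS]
)
NUC4_TABLE = np.stack(
    [encode_codon(c, EncodingScheme("NUC4-SEQ3")) for c in CODONS]
)
TARGET_TABLE = np.eye(21)


def encode_batch(codon_idx: np.ndarray, scheme: EncodingScheme) -> np.ndarray:
    """Vectorised batch encoding from canonical codon indices."""
    table = {
        "OHE64": OHE64_TABLE,
        "OHE12": OHE12_TABLE,
        "NUC4-SEQ3": NUC4_TABLE,
    }[scheme.name]
    return table[np.asarray(codon_idx)]


def encode_targets(aa_idx: np.ndarray) -> np.ndarray:
    """Batch of 21-bit one-hot targets from class indices."""
    return TARGET_TABLE[np.asarray(aa_idx)]


@dataclass
class EmbeddingSpec:
    """A learnable 64 x d codon embedding.

    Rows are initialised i.i.d. normal scaled by 1/sqrt(d) from the given
    seed; they are trained jointly with the decoder that consumes them.
    """

    d: int
    seed: int = 0
    matrix: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("embedding dimensionality d must be >= 1")
        if self.matrix is None:
            rng = np.random.default_rng(self.seed)
            self.matrix = rng.standard_normal((64, self.d)) / np.sqrt(self.d)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape != (64, self.d):
                raise ValueError(
                    f"embedding matrix shape {self.matrix.shape} != (64, {self.d})"
                )
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix must be finite")


def embed_codons(codon_idx: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    """Look up embedding rows for a batch of codon indices."""
    idx = np.asarray(codon_idx)
    if idx.size and (idx.min() < 0 or idx.max() >= 64):
        raise ValueError("codon indices must lie in [0, 64)")
    return spec.matrix[idx]


def export_embedding(spec: EmbeddingSpec, path: str | Path) -> None:
    """Write the embedding as a codon-labelled TSV (64 rows x d columns)."""
    df = pd.DataFrame(
        spec.matrix, index=CODONS, columns=[f"e{j}" for j in range(spec.d)]
    )
    df.to_csv(path, sep="\t", index_label="codon")
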