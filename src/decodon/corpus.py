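"""Training corpora: ORF extraction from transcripts, synthetic ORF generation,
usage statistics, class weights, and train/test batching.

Real mature-mRNA input is filtered down to valid open reading frames (start
``AUG``, a single terminal stop, length a multiple of 3, no internal in-frame
stop).  The synthetic generator emulates that structure directly: every ORF is
``AUG`` + body codons drawn i.i.d. from an unbalanced sense-codon usage
distribution + one stop codon, with lengths drawn from a right-skewed
log-normal model (median 400 codons by default, matching a ~1,200-nt mature
transcript).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AA_INDEX,
    AMINO_ACIDS,
    CODON_INDEX,
    CODONS,
    START_CODON,
    STOP_CODONS,
    STOP_SYMBOL,
    InvalidAlphabetError,
    codons_to_indices,
    normalize_sequence,
    standard_code,
    translate,
)

_CODON_ARR = np.array(CODONS)
_AA_OF_CODON = np.array([AA_INDEX[standard_code()[c]] for c in CODONS])
_AA_ARR = np.array(AMINO_ACIDS)
_STOP_IDX = np.array([CODON_INDEX[c] for c in STOP_CODONS])
_SENSE_IDX = np.array([i for i in range(64) if i not in set(_STOP_IDX)])

#: Deterministic priority when a sequence violates several filters at once.
REJECTION_PRIORITY = (
    "invalid-alphabet",
    "bad-length",
    "no-start",
    "no-terminal-stop",
    "internal-stop",
)


class EmptyCorpusError(ValueError):
    """An operation that needs at least one ORF received none."""


class ConfigurationError(ValueError):
    """A generator or split parameter is unusable."""


@dataclass
class OrfRecord:
    """A validated open reading frame with its ground-truth protein."""

    id: str
    rna: str
    protein: str
    _codons: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def codon_indices(self) -> np.ndarray:
        """Canonical codon indices of the RNA, cached after first use."""
        if self._codons is None:
            self._codons = np.asarray(codons_to_indices(self.rna), dtype=np.int16)
        return self._codons

    @property
    def aa_indices(self) -> np.ndarray:
        return _AA_OF_CODON[self.codon_indices]

    def __len__(self) -> int:
        return len(self.rna) // 3


@dataclass
class CodonUsageTable:
    """Relative frequencies over the 64 codons in canonical order."""

    freq: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (64,):
            raise ValueError(f"expected a 64-vector, got shape {self.freq.shape}")
        if (self.freq < 0).any():
            raise ValueError("codon frequencies must be non-negative")
        if abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError(f"codon frequencies sum to {self.freq.sum()}, not 1")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "CodonUsageTable":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise EmptyCorpusError("no codons counted")
        return cls(counts / total)

    def __getitem__(self, codon: str) -> float:
        return float(self.freq[CODON_INDEX[codon]])

    def argmax_codon(self) -> str:
        return CODONS[int(np.argmax(self.freq))]


@dataclass
class AminoAcidDistribution:
    """Relative frequencies over the 21 target classes (stop mark last)."""

    freq: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (21,):
            raise ValueError(f"expected a 21-vector, got shape {self.freq.shape}")
        if (self.freq < 0).any():
            raise ValueError("class frequencies must be non-negative")
        if abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError(f"class frequencies sum to {self.freq.sum()}, not 1")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "AminoAcidDistribution":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise EmptyCorpusError("no residues counted")
        return cls(counts / total)

    def __getitem__(self, symbol: str) -> float:
        return float(self.freq[AA_INDEX[symbol]])

    def argmax_symbol(self) -> str:
        return AMINO_ACIDS[int(np.argmax(self.freq))]


@dataclass
class ClassWeights:
    """Positive per-class loss weights, normalised to mean 1."""

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (21,):
            raise ValueError(f"expected a 21-vector, got shape {self.w.shape}")
        if not np.isfinite(self.w).all() or (self.w <= 0).any():
            raise ValueError("class weights must be finite and positive")


@dataclass
class PairDataset:
    """Codon/amino-acid pairs split at ORF level into train and test."""

    train_orfs: List[OrfRecord]
    test_orfs: List[OrfRecord]
    train_codons: np.ndarray  # int16, all training pairs flattened ORF by ORF
    train_aas: np.ndarray
    test_codons: np.ndarray
    test_aas: np.ndarray
    batch_size: int = 64

    @property
    def n_train_pairs(self) -> int:
        return len(self.train_codons)

    @property
    def n_test_pairs(self) -> int:
        return len(self.test_codons)

    def epoch_batches(
        self, rng: np.random.Generator, epoch_pairs: Optional[int] = None
    ) -> Iterable[Tuple[np.ndarray, np.ndarray]]:
        """Yield shuffled batches for one epoch.

        An epoch presents a fixed-size random subsample of ``epoch_pairs``
        training pairs (all of them, permuted, when ``epoch_pairs`` is None
        or exceeds the pool).  The final batch may be short.
        """
        n = self.n_train_pairs
        if epoch_pairs is None or epoch_pairs >= n:
            idx = rng.permutation(n)
        else:
            idx = rng.choice(n, size=epoch_pairs, replace=False)
        for start in range(0, len(idx), self.batch_size):
            sel = idx[start : start + self.batch_size]
            yield self.train_codons[sel], self.train_aas[sel]


# ---------------------------------------------------------------------------
# ORF extraction


def _check_orf(rna: str) -> Optional[str]:
    """Return a rejection reason for a normalised RNA string, or None."""
    if len(rna) % 3 != 0 or len(rna) < 6:
        return "bad-length"
    if not rna.startswith(START_CODON):
        return "no-start"
    if rna[-3:] not in STOP_CODONS:
        return "no-terminal-stop"
    for i in range(0, len(rna) - 3, 3):
        if rna[i : i + 3] in STOP_CODONS:
            return "internal-stop"
    return None


def extract_orfs(
    records: Sequence[Tuple[str, str]],
) -> Tuple[List[OrfRecord], List[Tuple[str, str]]]:
    """Validate raw transcript sequences against the four ORF filters.

    Each ``(id, sequence)`` input lands in exactly one of the two outputs.
    Sequences are normalised (case, T->U) first; a character outside the
    nucleotide alphabet rejects the record with reason ``invalid-alphabet``.
    Rejection reasons follow the fixed priority order
    ``invalid-alphabet > bad-length > no-start > no-terminal-stop >
    internal-stop``.
    """
    kept: List[OrfRecord] = []
    rejected: List[Tuple[str, str]] = []
    for rec_id, raw in records:
        try:
            rna = normalize_sequence(raw)
        except InvalidAlphabetError:
            rejected.append((rec_id, "invalid-alphabet"))
            continue
        reason = _check_orf(rna)
        if reason is not None:
            rejected.append((rec_id, reason))
        else:
            kept.append(OrfRecord(id=rec_id, rna=rna, protein=translate(rna)))
    return kept, rejected


# ---------------------------------------------------------------------------
# Synthetic generation


@dataclass
class LogNormalLengthModel:
    """Right-skewed ORF length model over total codon counts.

    Codon counts (start and stop included) are log-normal with the given
    median and log-scale sigma, rounded and clamped to ``[lo, hi]``.
    """

    median: float = 400.0
    sigma: float = 0.6
    lo: int = 10
    hi: int = 3000

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = rng.lognormal(mean=math.log(self.median), sigma=self.sigma, size=size)
        return np.clip(np.rint(draws).astype(int), self.lo, self.hi)


def generate_corpus(
    usage: CodonUsageTable,
    n_orfs: int,
    length_model: Optional[LogNormalLengthModel] = None,
    seed: int = 0,
) -> List[OrfRecord]:
    """Synthesise ``n_orfs`` valid ORF/protein pairs from a usage table.

    Each ORF is ``AUG`` followed by body codons drawn i.i.d. from ``usage``
    restricted and renormalised to the 61 sense codons, and terminated by a
    single stop codon drawn from ``usage`` restricted to the three stop
    codons.  The construction guarantees that every record passes
    :func:`extract_orfs` unchanged.  Identical seeds give identical corpora.
    """
    if n_orfs < 0:
        raise ConfigurationError("n_orfs must be non-negative")
    if n_orfs == 0:
        return []
    if length_model is None:
        length_model = LogNormalLengthModel()

    stop_mass = usage.freq[_STOP_IDX]
    if stop_mass.sum() <= 0:
        raise ConfigurationError("usage table has zero mass on stop codons")
    sense_mass = usage.freq[_SENSE_IDX]
    if sense_mass.sum() <= 0:
        raise ConfigurationError("usage table has zero mass on sense codons")
    stop_p = stop_mass / stop_mass.sum()
    sense_p = sense_mass / sense_mass.sum()

    rng = np.random.default_rng(seed)
    lengths = length_model.sample(rng, n_orfs)
    body_lengths = lengths - 2
    total_body = int(body_lengths.sum())
    body = _SENSE_IDX[rng.choice(len(_SENSE_IDX), size=total_body, p=sense_p)]
    stops = _STOP_IDX[rng.choice(3, size=n_orfs, p=stop_p)]

    start_idx = CODON_INDEX[START_CODON]
    offsets = np.concatenate([[0], np.cumsum(body_lengths)])
    records: List[OrfRecord] = []
    for i in range(n_orfs):
        codons = np.empty(lengths[i], dtype=np.int16)
        codons[0] = start_idx
        codons[1:-1] = body[offsets[i] : offsets[i + 1]]
        codons[-1] = stops[i]
        rna = "".join(_CODON_ARR[codons])
        protein = "".join(_AA_ARR[_AA_OF_CODON[codons]])
        records.append(
            OrfRecord(id=f"synth_{i:06d}", rna=rna, protein=protein, _codons=codons)
        )
    return records


# ---------------------------------------------------------------------------
# Usage statistics and weights


def codon_frequencies(orfs: Sequence[OrfRecord]) -> CodonUsageTable:
    """Empirical codon relative frequencies over a corpus."""
    if not orfs:
        raise EmptyCorpusError("cannot compute codon frequencies of an empty corpus")
    counts = np.zeros(64)
    for orf in orfs:
        counts += np.bincount(orf.codon_indices, minlength=64)
    return CodonUsageTable.from_counts(counts)


def aa_frequencies(orfs: Sequence[OrfRecord]) -> AminoAcidDistribution:
    """Empirical class relative frequencies over a corpus's proteins."""
    if not orfs:
        raise EmptyCorpusError("cannot compute class frequencies of an empty corpus")
    counts = np.zeros(21)
    for orf in orfs:
        counts += np.bincount(orf.aa_indices, minlength=21)
    return AminoAcidDistribution.from_counts(counts)


def class_weights(
    dist: AminoAcidDistribution, floor: float = 1e-6
) -> ClassWeights:
    """Inverse-frequency loss weights, normalised to mean 1.

    ``w[k] ∝ 1 / max(freq[k], floor)``; the floor keeps weights finite for
    classes absent from the corpus, which then receive the largest weight.
    """
    inv = 1.0 / np.maximum(dist.freq, floor)
    return ClassWeights(inv / inv.mean())


def split_and_batch(
    orfs: Sequence[OrfRecord],
    train_frac: float = 0.9,
    batch_size: int = 64,
    seed: int = 0,
) -> PairDataset:
    """Random ORF-level train/test partition and pair flattening.

    The split is performed on whole ORFs so no transcript contributes pairs
    to both sides; ``train_frac`` rounds to the nearest ORF count, clamped so
    that both sides are non-empty.
    """
    if len(orfs) < 2:
        raise ConfigurationError("need at least 2 ORFs to split")
    if not 0 < train_frac < 1:
        raise ConfigurationError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(orfs))
    n_train = int(np.clip(round(train_frac * len(orfs)), 1, len(orfs) - 1))
    train = [orfs[i] for i in order[:n_train]]
    test = [orfs[i] for i in order[n_train:]]

    def _flatten(group: List[OrfRecord]) -> Tuple[np.ndarray, np.ndarray]:
        cods = np.concatenate([o.codon_indices for o in group])
        return cods.astype(np.int16), _AA_OF_CODON[cods].astype(np.int8)

    tr_c, tr_a = _flatten(train)
    te_c, te_a = _flatten(test)
    return PairDataset(train, test, tr_c, tr_a, te_c, te_a, batch_size=batch_size)


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path: str | Path) -> List[Tuple[str, str]]:
    """Read transcript records as (id, sequence) tuples."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[Tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rec_id, description="") for rec_id, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_usage_table(path: str | Path) -> CodonUsageTable:
    """Load a codon-usage TSV with columns ``codon`` and ``frequency``.

    Codons may be written in DNA or RNA letters; frequencies are renormalised
    to sum to 1 so per-mille or percentage tables load unchanged.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"codon", "frequency"}.issubset(df.columns):
        raise ConfigurationError(
            f"usage table {path} must have header columns 'codon' and 'frequency'"
        )
    freq = np.zeros(64)
    for codon, value in zip(df["codon"], df["frequency"]):
        freq[CODON_INDEX[normalize_sequence(str(codon))]] = float(value)
    total = freq.sum()
    if total <= 0:
        raise ConfigurationError(f"usage table {path} has no positive frequencies")
    return CodonUsageTable(freq / total)


def write_usage_table(path: str | Path, usage: CodonUsageTable) -> None:
    pd.DataFrame({"codon": CODONS, "frequency": usage.freq}).to_csv(
        path, sep="\t", index=False
    )


def write_aa_distribution(path: str | Path, dist: AminoAcidDistribution) -> None:
    pd.DataFrame({"class": AMINO_ACIDS, "frequency": dist.freq}).to_csv(
        path, sep="\t", index=False
    )


def default_usage_table() -> CodonUsageTable:
    """The bundled human-like codon usage table."""
    ref = resources.files("decodon.data") / "human_codon_usage.tsv"
    with resources.as_file(ref) as path:
        return read_usage_table(path)
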