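"""Reading the decoding table out of a trained model and judging success.

The table is extracted by feeding all 64 codons directly to the decoder (not
by harvesting codons from batches): direct enumeration is exact and removes
batch-composition noise from the completeness judgement.  A table is
*unequivocal* when every codon's argmax call matches the reference code and
no row has an exact probability tie at its argmax; no minimum-margin
threshold is imposed, but per-row probabilities are exported so users can
apply their own.

Data efficiency — the cumulated number of training pairs presented before
the first unequivocal table — is read from the periodic checks in a
TrainingTrace, so its resolution is the check cadence times the batch size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .encoding import EmbeddingSpec
from .genetic_code import AA_INDEX, AMINO_ACIDS, CODONS, standard_code
from .models import Model

if TYPE_CHECKING:  # pragma: no cover
    from .training import TrainingTrace


@dataclass
class DecipheredTable:
    """Per-codon 21-class distributions with argmax calls.

    ``complete`` is equivalent to ``mismatches`` being empty; exact argmax
    ties are tracked separately because a tied row is not considered
    deciphered even when the tie-broken call happens to be right.
    """

    probs: np.ndarray  # 64 x 21 simplex rows in canonical codon order
    calls: np.ndarray  # 64 argmax class indices
    complete: bool
    mismatches: List[Tuple[str, str, str]]  # (codon, predicted, reference)
    tied_rows: List[str]

    def call_symbol(self, codon: str) -> str:
        return AMINO_ACIDS[int(self.calls[CODONS.index(codon)])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=CODONS, columns=AMINO_ACIDS)

    def to_code(self) -> Dict[str, str]:
        """The argmax table as a codon -> symbol dict (diffable vs reference)."""
        return {c: AMINO_ACIDS[int(k)] for c, k in zip(CODONS, self.calls)}


@dataclass
class EfficiencyResult:
    """Outcome of the minimal-pairs measurement for one run."""

    deciphered: bool
    pairs_at_deciphering: Optional[int]
    epoch_at_deciphering: Optional[int]
    check_cadence_pairs: int

    def censored_pairs(self, cap: int) -> int:
        """Pairs at deciphering, or the cap as a lower bound when censored."""
        return self.pairs_at_deciphering if self.deciphered else cap


def decode_table(
    model: Model, reference: Optional[Dict[str, str]] = None
) -> DecipheredTable:
    """Extract the current decoding table by enumerating all 64 codons."""
    if reference is None:
        reference = standard_code()
    probs = model.predict_proba(np.arange(64))
    calls = probs.argmax(axis=1)
    ref_idx = np.array([AA_INDEX[reference[c]] for c in CODONS])
    mismatches = [
        (CODONS[i], AMINO_ACIDS[int(calls[i])], AMINO_ACIDS[int(ref_idx[i])])
        for i in np.nonzero(calls != ref_idx)[0]
    ]
    row_max = probs.max(axis=1, keepdims=True)
    tied = np.nonzero((probs == row_max).sum(axis=1) > 1)[0]
    return DecipheredTable(
        probs=probs,
        calls=calls,
        complete=not mismatches,
        mismatches=mismatches,
        tied_rows=[CODONS[i] for i in tied],
    )


def is_unequivocal(
    table: DecipheredTable, reference: Optional[Dict[str, str]] = None
) -> bool:
    """True iff every argmax call matches the reference and no row is tied."""
    if reference is None:
        reference = standard_code()
    ref_idx = np.array([AA_INDEX[reference[c]] for c in CODONS])
    if not np.array_equal(table.calls, ref_idx):
        return False
    return not table.tied_rows


def data_efficiency(
    trace: "TrainingTrace", reference: Optional[Dict[str, str]] = None
) -> EfficiencyResult:
    """Cumulated pairs at the earliest unequivocal deciphering check.

    ``reference`` other than the standard code re-judges the stored snapshot
    tables; with the default reference the cheap per-check verdicts recorded
    during training are used directly.
    """
    if not trace.checks:
        raise ValueError("trace contains no deciphering checks")
    cadence_pairs = trace.config.check_every * trace.config.batch_size
    if reference is None:
        for check in trace.checks:
            if check.unequivocal:
                return EfficiencyResult(
                    True, check.cumulated_pairs, check.epoch, cadence_pairs
                )
    else:
        for snap in trace.snapshots:
            if is_unequivocal(snap.table, reference):
                epoch = next(
                    (c.epoch for c in trace.checks if c.iteration >= snap.iteration),
                    trace.checks[-1].epoch,
                )
                return EfficiencyResult(
                    True, snap.cumulated_pairs, epoch, cadence_pairs
                )
    return EfficiencyResult(False, None, None, cadence_pairs)


def synonymy_clustering_score(
    spec: EmbeddingSpec, code: Optional[Dict[str, str]] = None
) -> float:
    """Mean silhouette of embedding rows grouped by amino-acid class.

    Synonymous codons sharing a class should cluster in embedding space;
    the silhouette (Euclidean distance) quantifies that.  Codons whose class
    has a single member (M, W) carry no synonymy information and are
    excluded.  A fully degenerate embedding (all rows identical) scores 0
    by convention.
    """
    if code is None:
        code = standard_code()
    labels = np.array([AA_INDEX[code[c]] for c in CODONS])
    sizes = np.bincount(labels, minlength=21)
    keep = sizes[labels] >= 2
    if not keep.any() or len(np.unique(labels[keep])) < 2:
        raise ValueError("synonymy score undefined: no multi-codon classes")
    X = spec.matrix[keep]
    if np.allclose(X, X[0]):
        return 0.0
    return float(silhouette_score(X, labels[keep], metric="euclidean"))


def export_snapshots(trace: "TrainingTrace", out_dir: str | Path) -> List[Path]:
    """Write one probability CSV and one heatmap PNG per stored snapshot.

    Filenames carry the iteration and cumulated pair count.  CSV rows are
    codon-labelled simplex rows over the 21 class columns.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create snapshot directory {out}: {exc}") from exc
    written: List[Path] = []
    for snap in trace.snapshots:
        stem = f"table_iter{snap.iteration:08d}_pairs{snap.cumulated_pairs:010d}"
        csv_path = out / f"{stem}.csv"
        snap.table.to_frame().to_csv(csv_path)
        fig, ax = plt.subplots(figsize=(6, 10))
        ax.imshow(snap.table.probs, aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(21), AMINO_ACIDS)
        ax.set_yticks(range(64), CODONS, fontsize=4)
        ax.set_xlabel("class")
        ax.set_title(
            f"iteration {snap.iteration}  ({snap.cumulated_pairs:,} pairs)"
        )
        png_path = out / f"{stem}.png"
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.extend([csv_path, png_path])
    return written


def export_final_table(table: DecipheredTable, path: str | Path) -> None:
    """Two-column TSV (codon, class call) for direct diff against the code."""
    pd.DataFrame(
        {"codon": CODONS, "amino_acid": [AMINO_ACIDS[int(k)] for k in table.calls]}
    ).to_csv(path, sep="\t", index=False)
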