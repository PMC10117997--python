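"""Optimisation loop: class-weighted cross-entropy, Adam, and trace logging.

An *epoch* here is one pass over a fixed-size random subsample of training
pairs (561,600 by default), resampled each epoch from the training pool —
deciphering is data-efficiency benchmarking, so the unit of progress is the
cumulated number of codon/amino-acid pairs presented, not corpus passes.
Every ``check_every`` iterations the current 64-codon decoding table is
extracted and judged against the reference code; the trace records these
checks so the minimal-pairs metric can be read off afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .corpus import ClassWeights, PairDataset
from .deciphering import DecipheredTable, decode_table, is_unequivocal
from .encoding import encode_targets
from .genetic_code import AA_INDEX, CODONS, standard_code
from .models import Model, softmax

_EPS = 1e-12


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; carries the partial trace."""

    def __init__(self, message: str, trace: "TrainingTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``learning_rate`` defaults to 0.05 (suits the MLP families); recurrent
    readers are conventionally run at 0.005.  ``epoch_pairs`` must be a
    multiple of ``batch_size``.  ``max_pairs``, when set, caps the cumulated
    pair count regardless of the epoch cap.  ``check_every`` sets the
    deciphering-check cadence in iterations; its granularity bounds the
    resolution of the pairs-to-deciphering metric.
    """

    learning_rate: float = 0.05
    max_epochs: int = 40
    batch_size: int = 64
    epoch_pairs: int = 561_600
    weights: Optional[ClassWeights] = None
    seed: int = 0
    check_every: int = 50
    snapshot_every_checks: int = 20
    stop_on_deciphering: bool = True
    max_pairs: Optional[int] = None
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epoch_pairs % self.batch_size != 0:
            raise ValueError("epoch_pairs must be a multiple of batch_size")


@dataclass
class Snapshot:
    iteration: int
    cumulated_pairs: int
    table: DecipheredTable


@dataclass
class DecipherCheck:
    iteration: int
    epoch: int
    cumulated_pairs: int
    unequivocal: bool
    n_mismatches: int


@dataclass
class TrainingTrace:
    """Per-iteration log plus periodic deciphering checks and snapshots."""

    config: TrainConfig
    iterations: List[int] = field(default_factory=list)
    epochs: List[int] = field(default_factory=list)
    cumulated_pairs: List[int] = field(default_factory=list)
    losses: List[float] = field(default_factory=list)
    train_accuracies: List[float] = field(default_factory=list)
    test_accuracies: List[Tuple[int, float]] = field(default_factory=list)
    checks: List[DecipherCheck] = field(default_factory=list)
    snapshots: List[Snapshot] = field(default_factory=list)
    final_test_accuracy: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        test_by_epoch = dict(self.test_accuracies)
        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "epoch": self.epochs,
                "cumulated_pairs": self.cumulated_pairs,
                "loss": self.losses,
                "train_accuracy": self.train_accuracies,
                "test_accuracy": [test_by_epoch.get(e) for e in self.epochs],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def weighted_cross_entropy(
    pred: np.ndarray, target: np.ndarray, weights: Optional[ClassWeights] = None
) -> float:
    """Mean over the batch of ``-w[class] * log p[class]``.

    ``pred`` holds simplex rows, ``target`` one-hot rows (or class indices).
    Without weights all classes count 1.  Probabilities are floored at 1e-12
    inside the log.
    """
    pred = np.atleast_2d(pred)
    target = np.asarray(target)
    cls = target.argmax(axis=-1) if target.ndim == pred.ndim else np.atleast_1d(target)
    p_true = pred[np.arange(len(cls)), cls]
    w = np.ones(21) if weights is None else weights.w
    return float(np.mean(-w[cls] * np.log(np.maximum(p_true, _EPS))))


def accuracy(pred: np.ndarray, target: np.ndarray) -> float:
    """Fraction of rows whose argmax class matches the target.

    Equivalent to averaging the dot product of the one-hot argmax prediction
    with the one-hot target.  Ties go to the lowest class index.
    """
    pred = np.atleast_2d(pred)
    target = np.asarray(target)
    cls = target.argmax(axis=-1) if target.ndim == pred.ndim else np.atleast_1d(target)
    return float(np.mean(pred.argmax(axis=-1) == cls))


class Adam:
    """Adaptive moment estimation; updates parameters in place."""

    def __init__(self, model: Model, config: TrainConfig):
        self.cfg = config
        self.m: Dict[str, np.ndarray] = {
            k: np.zeros_like(v) for k, v in model.params.items()
        }
        self.v: Dict[str, np.ndarray] = {
            k: np.zeros_like(v) for k, v in model.params.items()
        }
        self.t = 0

    def step(self, model: Model, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        c = self.cfg
        b1c = 1.0 - c.adam_beta1**self.t
        b2c = 1.0 - c.adam_beta2**self.t
        for k, p in model.params.items():
            g = grads[k]
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            p -= c.learning_rate * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + c.adam_eps
            )


def _test_accuracy_from_table(table: DecipheredTable, dataset: PairDataset) -> float:
    """Argmax translation accuracy over all test pairs.

    The decoder maps each codon to a fixed class, so test accuracy is the
    codon-count-weighted fraction of correctly decoded codons.
    """
    if dataset.n_test_pairs == 0:
        return float("nan")
    counts = np.bincount(dataset.test_codons, minlength=64)
    code = standard_code()
    ref = np.array([AA_INDEX[code[c]] for c in CODONS])
    return float(counts[table.calls == ref].sum() / counts.sum())


def evaluate_test_accuracy(model: Model, dataset: PairDataset) -> float:
    """Convenience wrapper: decode the table, score it on the test pairs."""
    return _test_accuracy_from_table(decode_table(model), dataset)


def train(model: Model, dataset: PairDataset, config: TrainConfig) -> TrainingTrace:
    """Run Adam on weighted cross-entropy and log a full TrainingTrace.

    Stops at the epoch cap, at ``max_pairs`` if set, or — by default — at
    the first deciphering check whose table is unequivocally complete.
    Identical seeds and inputs reproduce the trace exactly.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, config)
    trace = TrainingTrace(config=config)
    w = np.ones(21) if config.weights is None else config.weights.w
    reference = standard_code()

    # Judge the untrained table first: a model that already implements the
    # code (e.g. the oracle) deciphers at 0 cumulated pairs.
    table0 = decode_table(model)
    ok0 = is_unequivocal(table0, reference)
    trace.checks.append(DecipherCheck(0, 0, 0, ok0, len(table0.mismatches)))
    if ok0:
        trace.snapshots.append(Snapshot(0, 0, table0))

    iteration = 0
    pairs = 0
    done = False
    for epoch in range(1, config.max_epochs + 1):
        for codon_idx, aa_idx in dataset.epoch_batches(rng, config.epoch_pairs):
            iteration += 1
            X = model.prepare(codon_idx)
            logits = model.forward_logits(X, cache=True)
            probs = softmax(logits)
            B = len(aa_idx)
            cls = np.asarray(aa_idx, dtype=int)
            p_true = probs[np.arange(B), cls]
            loss = float(np.mean(-w[cls] * np.log(np.maximum(p_true, _EPS))))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at iteration {iteration}", trace
                )
            dlogits = (probs - encode_targets(cls)) * (w[cls] / B)[:, None]
            opt.step(model, model.backward(dlogits))

            pairs += B
            trace.iterations.append(iteration)
            trace.epochs.append(epoch)
            trace.cumulated_pairs.append(pairs)
            trace.losses.append(loss)
            trace.train_accuracies.append(
                float(np.mean(probs.argmax(axis=-1) == cls))
            )

            if iteration % config.check_every == 0:
                table = decode_table(model)
                ok = is_unequivocal(table, reference)
                trace.checks.append(
                    DecipherCheck(iteration, epoch, pairs, ok, len(table.mismatches))
                )
                first_ok = ok and not any(c.unequivocal for c in trace.checks[:-1])
                if first_ok or len(trace.checks) % config.snapshot_every_checks == 1:
                    trace.snapshots.append(Snapshot(iteration, pairs, table))
                if ok and config.stop_on_deciphering:
                    done = True
            if config.max_pairs is not None and pairs >= config.max_pairs:
                done = True
            if done:
                break
        table = decode_table(model)
        acc = _test_accuracy_from_table(table, dataset)
        trace.test_accuracies.append((epoch, acc))
        trace.final_test_accuracy = acc
        if done:
            break
    if not trace.snapshots or trace.snapshots[-1].iteration != iteration:
        trace.snapshots.append(Snapshot(iteration, pairs, decode_table(model)))
    return trace
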