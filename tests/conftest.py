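import numpy as np
import pytest

from decodon.corpus import (
    default_usage_table,
    generate_corpus,
    split_and_batch,
)


@pytest.fixture(scope="session")
def usage():
    return default_usage_table()


@pytest.fixture(scope="session")
def small_corpus(usage):
    """A quick 300-ORF synthetic corpus for unit-level checks."""
    return generate_corpus(usage, 300, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    return split_and_batch(small_corpus, seed=8)


@pytest.fixture(scope="session")
def bench_corpus(usage):
    """The study-scale corpus: 5,000 ORFs, human-like usage, median 400 codons."""
    return generate_corpus(usage, 5000, seed=1)


@pytest.fixture(scope="session")
def bench_dataset(bench_corpus):
    return split_and_batch(bench_corpus, train_frac=0.9, batch_size=64, seed=2)


@pytest.fixture
def toy_fasta(tmp_path):
    """Four transcripts: one valid ORF, three each violating one filter."""
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">ok\nATGGCTTAA\n"
        ">nostop\nATGGCTGCT\n"
        ">internal\nATGTAAGCTTAA\n"
        ">badlen\nATGGCTTA\n"
    )
    return path
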