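"""ORF filtering, synthetic generation, usage statistics, and batching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decodon.corpus import (
    AminoAcidDistribution,
    ConfigurationError,
    CodonUsageTable,
    EmptyCorpusError,
    LogNormalLengthModel,
    aa_frequencies,
    class_weights,
    codon_frequencies,
    extract_orfs,
    generate_corpus,
    read_usage_table,
    split_and_batch,
    write_usage_table,
)
from decodon.genetic_code import AA_INDEX, CODON_INDEX, CODONS, standard_code


class TestExtractOrfs:
    @pytest.mark.parametrize(
        "seq,reason",
        [
            ("AUGGCUUAA", None),
            ("atggcttaa", None),  # DNA lower case accepted after normalisation
            ("AUGGCUGCU", "no-terminal-stop"),
            ("AUGUAAGCUUAA", "internal-stop"),
            ("AUGGCUUA", "bad-length"),
            ("GCUGCUUAA", "no-start"),
            ("AUGNNNUAA", "invalid-alphabet"),
        ],
    )
    def test_filters(self, seq, reason):
        kept, rejected = extract_orfs([("x", seq)])
        if reason is None:
            assert len(kept) == 1 and not rejected
            assert kept[0].protein == "MA*"
        else:
            assert not kept and rejected == [("x", reason)]

    def test_every_input_lands_in_exactly_one_output(self):
        records = [("a", "AUGGCUUAA"), ("b", "AUG"), ("c", "AUGUGA")]
        kept, rejected = extract_orfs(records)
        assert len(kept) + len(rejected) == len(records)

    def test_empty_input(self):
        assert extract_orfs([]) == ([], [])


class TestGenerateCorpus:
    def test_zero_orfs(self, usage):
        assert generate_corpus(usage, 0, seed=0) == []

    def test_roundtrip_all_records_pass_filters(self, usage):
        orfs = generate_corpus(usage, 100, seed=5)
        kept, rejected = extract_orfs([(o.id, o.rna) for o in orfs])
        assert len(kept) == 100 and not rejected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_roundtrip_any_seed(self, usage, seed):
        model = LogNormalLengthModel(median=30, lo=5, hi=100)
        orfs = generate_corpus(usage, 20, model, seed=seed)
        _, rejected = extract_orfs([(o.id, o.rna) for o in orfs])
        assert not rejected

    def test_determinism(self, usage):
        a = generate_corpus(usage, 10, seed=3)
        b = generate_corpus(usage, 10, seed=3)
        assert [o.rna for o in a] == [o.rna for o in b]

    def test_protein_matches_translation(self, usage):
        from decodon.genetic_code import translate

        for orf in generate_corpus(usage, 20, seed=4):
            assert orf.protein == translate(orf.rna)

    def test_body_frequencies_match_usage_tv_002(self, usage, bench_corpus):
        # 5,000 ORFs, median 400 codons: empirical body-codon frequencies
        # within total-variation distance 0.02 of renormalised sense usage
        counts = np.zeros(64)
        for orf in bench_corpus:
            body = orf.codon_indices[1:-1]
            counts += np.bincount(body, minlength=64)
        emp = counts / counts.sum()
        sense = usage.freq.copy()
        for stop in ("UAA", "UAG", "UGA"):
            sense[CODON_INDEX[stop]] = 0.0
        sense /= sense.sum()
        assert 0.5 * np.abs(emp - sense).sum() < 0.02

    def test_zero_stop_mass_is_configuration_error(self):
        freq = np.zeros(64)
        freq[CODON_INDEX["GCU"]] = 1.0
        with pytest.raises(ConfigurationError):
            generate_corpus(CodonUsageTable(freq), 5, seed=0)


class TestFrequencies:
    def test_single_orf_counts(self):
        kept, _ = extract_orfs([("a", "AUGUAA")])
        cf = codon_frequencies(kept)
        assert cf["AUG"] == 0.5 and cf["UAA"] == 0.5
        af = aa_frequencies(kept)
        assert af["M"] == 0.5 and af["*"] == 0.5

    def test_empty_corpus_errors(self):
        with pytest.raises(EmptyCorpusError):
            codon_frequencies([])
        with pytest.raises(EmptyCorpusError):
            aa_frequencies([])

    def test_pushforward_identity(self, small_corpus):
        # class frequencies == codon frequencies pushed through the code
        cf = codon_frequencies(small_corpus)
        af = aa_frequencies(small_corpus)
        code = standard_code()
        pushed = np.zeros(21)
        for codon in CODONS:
            pushed[AA_INDEX[code[codon]]] += cf[codon]
        np.testing.assert_allclose(af.freq, pushed, atol=1e-12)

    def test_distributions_sum_to_one(self, small_corpus):
        assert abs(codon_frequencies(small_corpus).freq.sum() - 1) < 1e-9
        assert abs(aa_frequencies(small_corpus).freq.sum() - 1) < 1e-9


class TestClassWeights:
    def test_uniform_distribution_gives_unit_weights(self):
        w = class_weights(AminoAcidDistribution(np.full(21, 1 / 21)))
        np.testing.assert_allclose(w.w, 1.0)

    def test_inverse_proportionality(self):
        freq = np.full(21, 0.0)
        freq[0], freq[1] = 0.8, 0.2
        w = class_weights(AminoAcidDistribution(freq), floor=1e-6)
        assert w.w[1] / w.w[0] == pytest.approx(4.0)

    def test_zero_frequency_class_gets_largest_finite_weight(self):
        freq = np.full(21, 1 / 20)
        freq[20] = 0.0
        w = class_weights(AminoAcidDistribution(freq), floor=1e-6)
        assert np.isfinite(w.w).all()
        assert w.w.argmax() == 20

    def test_scale_invariance(self, small_corpus):
        dist = aa_frequencies(small_corpus)
        # weights depend on relative frequencies only
        doubled = AminoAcidDistribution((2 * dist.freq) / (2 * dist.freq).sum())
        np.testing.assert_allclose(
            class_weights(dist).w, class_weights(doubled).w
        )

    def test_mean_one_normalisation(self, small_corpus):
        assert class_weights(aa_frequencies(small_corpus)).w.mean() == pytest.approx(1.0)


class TestSplitAndBatch:
    def test_orf_level_partition(self, small_corpus):
        ds = split_and_batch(small_corpus, train_frac=0.9, seed=0)
        train_ids = {o.id for o in ds.train_orfs}
        test_ids = {o.id for o in ds.test_orfs}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {o.id for o in small_corpus}

    def test_ten_orfs_give_nine_one(self, usage):
        orfs = generate_corpus(usage, 10, seed=1)
        ds = split_and_batch(orfs, train_frac=0.9, seed=0)
        assert len(ds.train_orfs) == 9 and len(ds.test_orfs) == 1

    def test_determinism(self, small_corpus):
        a = split_and_batch(small_corpus, seed=5)
        b = split_and_batch(small_corpus, seed=5)
        assert [o.id for o in a.train_orfs] == [o.id for o in b.train_orfs]
        ra, rb = np.random.default_rng(9), np.random.default_rng(9)
        batch_a = next(iter(a.epoch_batches(ra, 640)))
        batch_b = next(iter(b.epoch_batches(rb, 640)))
        np.testing.assert_array_equal(batch_a[0], batch_b[0])

    def test_batch_sizes_and_pair_counters(self, small_corpus):
        ds = split_and_batch(small_corpus, batch_size=64, seed=0)
        rng = np.random.default_rng(0)
        batches = list(ds.epoch_batches(rng, epoch_pairs=640))
        assert len(batches) == 10
        assert all(len(c) == 64 for c, _ in batches)
        assert sum(len(c) for c, _ in batches) == 640

    def test_pairs_consistent_with_code(self, small_dataset):
        code = standard_code()
        ref = np.array([AA_INDEX[code[c]] for c in CODONS])
        np.testing.assert_array_equal(
            small_dataset.train_aas, ref[small_dataset.train_codons]
        )

    def test_too_few_orfs(self, usage):
        orfs = generate_corpus(usage, 1, seed=0)
        with pytest.raises(ConfigurationError):
            split_and_batch(orfs)


class TestUsageTableIO:
    def test_roundtrip(self, usage, tmp_path):
        path = tmp_path / "usage.tsv"
        write_usage_table(path, usage)
        back = read_usage_table(path)
        np.testing.assert_allclose(back.freq, usage.freq, atol=1e-12)

    def test_bundled_table_is_human_like(self, usage):
        # strongly biased (GAG-most-frequent mirrors the human transcriptome)
        assert usage.argmax_codon() == "GAG"
        assert usage["GAG"] > 3 * usage["UUA"]

    def test_header_required(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("AAA\t0.5\nUUU\t0.5\n")
        with pytest.raises(ConfigurationError):
            read_usage_table(path)
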