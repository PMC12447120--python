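"""Read counting, trimmed means and expression summarization."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kmerquant as kq

from .conftest import oracle_extract, oracle_trimmed_mean, oracle_unique_index, rc


@pytest.fixture(scope="module")
def toy_index(toy_dataset, mask33):
    genome, annotation = toy_dataset
    return kq.build_unique_index(genome, annotation, mask33)


def gene_reads(genome, gene, n, length, seed):
    """Error-free reads drawn uniformly from one gene span, both strands."""
    rng = np.random.default_rng(seed)
    seq = genome[gene.chrom][gene.start : gene.end]
    out = []
    for _ in range(n):
        start = rng.integers(0, len(seq) - length + 1)
        read = seq[start : start + length]
        out.append(rc(read) if rng.random() < 0.5 else read)
    return out


class TestCountReads:
    def test_single_window_read_increments_its_gene(self, toy_dataset, toy_index):
        genome, annotation = toy_dataset
        g3 = annotation[2]
        window = genome[g3.chrom][g3.start : g3.start + 33]
        table = kq.count_reads([window], toy_index)
        assert table.reads_processed == 1
        assert table.windows_matched == 1
        (gene_counts,) = [
            (g, c) for g, c in table.as_dict().items() if c
        ]
        assert gene_counts[0] == "g3"

    def test_short_and_all_ambiguous_reads_count_nothing(self, toy_index):
        table = kq.count_reads(["ACGT", "N" * 50], toy_index)
        assert table.reads_processed == 2
        assert table.windows_matched == 0

    def test_counts_match_brute_force_recount(self, toy_dataset, toy_index):
        genome, annotation = toy_dataset
        g4 = annotation[3]
        reads = gene_reads(genome, g4, 500, 70, seed=11)
        table = kq.count_reads(reads, toy_index)
        # oracle: scan each read independently, tally canonical k-mers
        # found in a brute-force unique index
        oracle_idx = oracle_unique_index(
            genome, annotation, toy_index.mask.pattern, True
        )
        expected: dict[str, int] = {}
        for read in reads:
            for kmer, _ in oracle_extract(read, toy_index.mask.pattern, True):
                if kmer in oracle_idx:
                    expected[kmer] = expected.get(kmer, 0) + 1
        got = {
            kmer: c for gene, kc in table.as_dict().items() for kmer, c in kc.items()
        }
        assert got == expected
        assert table.windows_matched == sum(expected.values())

    def test_order_and_chunking_invariance(self, toy_dataset, toy_index):
        genome, annotation = toy_dataset
        reads = gene_reads(genome, annotation[2], 300, 60, seed=3)
        whole = kq.count_reads(reads, toy_index)
        permuted = kq.count_reads(reads[::-1], toy_index)
        split = kq.count_reads(reads[:97], toy_index) + kq.count_reads(reads[97:], toy_index)
        assert np.array_equal(whole.counts, permuted.counts)
        assert np.array_equal(whole.counts, split.counts)

    def test_reverse_complementing_reads_leaves_counts_unchanged(
        self, toy_dataset, toy_index
    ):
        genome, annotation = toy_dataset
        reads = gene_reads(genome, annotation[3], 200, 64, seed=5)
        fwd = kq.count_reads(reads, toy_index)
        rev = kq.count_reads([rc(r) for r in reads], toy_index)
        assert np.array_equal(fwd.counts, rev.counts)


class TestCountSample:
    def test_plain_and_gzipped_fastq_agree(self, toy_dataset, toy_index, tmp_path):
        genome, annotation = toy_dataset
        reads = gene_reads(genome, annotation[0], 100, 60, seed=7)
        plain, gz = tmp_path / "s.fastq", tmp_path / "s.fastq.gz"
        text = "".join(
            f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n" for i, seq in enumerate(reads)
        )
        plain.write_text(text)
        with gzip.open(gz, "wt") as fh:
            fh.write(text)
        t_plain = kq.count_sample(plain, toy_index)
        t_gz = kq.count_sample(gz, toy_index)
        assert np.array_equal(t_plain.counts, t_gz.counts)
        assert t_plain.reads_processed == 100

    def test_malformed_record_reported_with_number(self, toy_index, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nIIII\n")  # missing '+'
        with pytest.raises(kq.InputError, match="record 2"):
            kq.count_sample(bad, toy_index)


class TestTrimmedMean:
    def test_drops_one_from_each_tail(self):
        assert kq.trimmed_mean([1, 2, 3, 4, 100], 0.2) == 3.0

    def test_zero_trim_is_arithmetic_mean(self):
        vals = [3.5, 1.0, 2.5]
        assert kq.trimmed_mean(vals, 0.0) == pytest.approx(np.mean(vals))

    def test_empty_collection_rejected(self):
        with pytest.raises(kq.ContractError):
            kq.trimmed_mean([], 0.1)

    def test_trim_fraction_half_rejected(self):
        with pytest.raises(kq.ContractError):
            kq.trimmed_mean([1, 2], 0.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=50),
        frac=st.floats(0, 0.49),
    )
    def test_matches_sort_slice_mean_oracle(self, values, frac):
        got = kq.trimmed_mean(values, frac)
        assert got == pytest.approx(oracle_trimmed_mean(values, frac), rel=1e-12, abs=1e-9)
        assert min(values) - 1e-9 <= got <= max(values) + 1e-9


class TestSummarizeExpression:
    @pytest.fixture()
    def handmade_index(self):
        mask = kq.parse_mask("###")
        codes = np.array([5, 17, 40, 51], dtype=np.int64)  # arbitrary, sorted
        return kq.UniqueKmerIndex(
            mask=mask, canonical=False, gene_ids=["gA", "gB", "gC"],
            codes=codes, gene_idx=np.array([0, 0, 0, 1]),
            multiplicity=np.ones(4, dtype=np.int64),
        )

    def test_zero_count_kmers_enter_the_average(self, handmade_index):
        table = kq.KmerCountTable(
            "s1", handmade_index, np.array([0, 0, 10, 4], dtype=np.int64)
        )
        matrix = kq.summarize_expression([table], handmade_index, trim_fraction=0.0)
        assert matrix.data.loc["gA", "s1"] == pytest.approx(10 / 3)
        assert matrix.data.loc["gB", "s1"] == pytest.approx(4.0)

    def test_gene_without_kmers_is_absent_not_zero(self, handmade_index):
        table = kq.KmerCountTable("s1", handmade_index, np.zeros(4, dtype=np.int64))
        matrix = kq.summarize_expression([table], handmade_index, 0.0)
        assert np.isnan(matrix.data.loc["gC", "s1"])
        assert matrix.data.loc["gA", "s1"] == 0.0

    def test_identical_samples_give_identical_columns(self, toy_dataset, toy_index):
        genome, annotation = toy_dataset
        reads = gene_reads(genome, annotation[1], 150, 60, seed=9)
        t1 = kq.count_reads(reads, toy_index, sample_id="a")
        t2 = kq.count_reads(reads, toy_index, sample_id="b")
        matrix = kq.summarize_expression([t1, t2], toy_index, 0.05)
        assert matrix.data["a"].equals(matrix.data["b"])

    def test_foreign_count_table_rejected(self, toy_index, handmade_index):
        table = kq.KmerCountTable("s1", handmade_index, np.zeros(4, dtype=np.int64))
        with pytest.raises(kq.ValidationError):
            kq.summarize_expression([table], toy_index, 0.0)
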