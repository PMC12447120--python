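"""Read counting against the unique-k-mer index and expression summarization.

Each read is scanned window by window; every (canonical) masked k-mer
that is present in the index increments that k-mer's count under its
gene.  Counting is alignment-free and order-invariant: permuting reads
or splitting a FASTQ into parts and summing the tables yields identical
counts.  Per gene and sample, the per-k-mer counts — over the gene's
*full* indexed k-mer set, unobserved k-mers contributing zeros so the
denominator is fixed across samples — are summarized to one expression
value by a trimmed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError, InputError, ValidationError
from .index import UniqueKmerIndex
from .io import iter_fastq_seqs
from .mask import encode_sequence, window_codes

_CHUNK_READS = 8192


@dataclass
class KmerCountTable:
    """Per-sample occurrence counts of indexed k-mers.

    ``counts`` is aligned with the index's entry arrays (one slot per
    indexed k-mer, zeros kept), so tables from the same index can be
    added cell-wise and summarized with a fixed denominator.
    """

    sample_id: str
    index: UniqueKmerIndex
    counts: np.ndarray
    reads_processed: int = 0
    index_digest: str = field(default="")

    def __post_init__(self) -> None:
        if not self.index_digest:
            self.index_digest = self.index.digest

    @property
    def windows_matched(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, dict[str, int]]:
        """Nested gene -> k-mer -> count view (nonzero counts only)."""
        out: dict[str, dict[str, int]] = {g: {} for g in self.index.gene_ids}
        kmers = self.index.kmer_strings()
        for pos in np.flatnonzero(self.counts):
            gene = self.index.gene_ids[int(self.index.gene_idx[pos])]
            out[gene][kmers[pos]] = int(self.counts[pos])
        return out

    def __add__(self, other: "KmerCountTable") -> "KmerCountTable":
        if self.index_digest != other.index_digest:
            raise ValidationError("cannot add count tables from different indexes")
        return KmerCountTable(
            sample_id=self.sample_id,
            index=self.index,
            counts=self.counts + other.counts,
            reads_processed=self.reads_processed + other.reads_processed,
            index_digest=self.index_digest,
        )


def _count_chunk(
    seqs: Sequence[str], index: UniqueKmerIndex, counts: np.ndarray
) -> int:
    """Count one batch of reads; returns the number of matched windows.

    Reads are joined with a spacer of ``w - 1`` ambiguous bases so the
    whole batch is scanned in one vectorized pass: every window crossing
    a read boundary necessarily has a spacer base at a considered
    position (masks start and end on considered positions) and is
    dropped as invalid.
    """
    mask = index.mask
    spacer = "N" * (mask.window - 1)
    joined = spacer.join(seqs)
    fwd, rc, valid = window_codes(encode_sequence(joined), mask)
    codes = np.minimum(fwd, rc) if index.canonical else fwd
    codes = codes[valid]
    if codes.size == 0 or len(index) == 0:
        return 0
    pos = np.searchsorted(index.codes, codes)
    pos[pos == len(index)] = 0
    hit = index.codes[pos] == codes
    matched = pos[hit]
    np.add.at(counts, matched, 1)
    return int(matched.size)


def count_reads(
    seqs: Iterable[str], index: UniqueKmerIndex, sample_id: str = "sample"
) -> KmerCountTable:
    """Count indexed k-mer occurrences over an iterable of read sequences."""
    counts = np.zeros(len(index), dtype=np.int64)
    n_reads = 0
    batch: list[str] = []
    for seq in seqs:
        batch.append(seq)
        n_reads += 1
        if len(batch) >= _CHUNK_READS:
            _count_chunk(batch, index, counts)
            batch = []
    if batch:
        _count_chunk(batch, index, counts)
    return KmerCountTable(sample_id=sample_id, index=index, counts=counts,
                          reads_processed=n_reads)


def count_sample(
    fastq_path, index: UniqueKmerIndex, sample_id: str | None = None
) -> KmerCountTable:
    """Stream a FASTQ file (plain or gzipped) into a count table.

    Read qualities are ignored; reads shorter than the mask window
    contribute nothing.  Malformed records raise :class:`InputError`
    naming the record number.
    """
    if sample_id is None:
        sample_id = str(fastq_path)
    return count_reads(iter_fastq_seqs(fastq_path), index, sample_id=sample_id)


def trimmed_mean(values, trim_fraction: float) -> float:
    """Symmetric trimmed mean: drop ``floor(trim_fraction * n)`` values
    from each end of the sorted data, then average the rest.

    ``trim_fraction`` is the per-tail fraction and must lie in [0, 0.5).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ContractError("trimmed_mean of an empty collection")
    if not 0 <= trim_fraction < 0.5:
        raise ContractError(f"trim_fraction {trim_fraction} outside [0, 0.5)")
    return float(stats.trim_mean(arr, trim_fraction))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``data`` is a DataFrame indexed by gene_id with one column per
    sample.  Genes without any indexed k-mer are *absent* and carry NaN
    (written as ``NA``), never a fake zero.  ``scale`` records whether
    values are raw trimmed-mean counts or normalized log2.
    """

    data: pd.DataFrame
    scale: str = "raw"  # "raw" | "normalized-log2"

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def quantifiable(self) -> pd.Series:
        return self.data.notna().all(axis=1)


def summarize_expression(
    tables: Sequence[KmerCountTable],
    index: UniqueKmerIndex,
    trim_fraction: float = 0.05,
) -> ExpressionMatrix:
    """Collapse per-k-mer counts to one raw expression value per gene/sample.

    Cell (g, s) is the trimmed mean over *all* of gene g's indexed
    k-mers (zeros included).  Genes with no indexed k-mers are absent
    (NaN).  All tables must have been counted against ``index``.
    """
    digest = index.digest
    for t in tables:
        if t.index_digest != digest:
            raise ValidationError(
                f"count table {t.sample_id!r} was built against a different index"
            )
    order = np.argsort(index.gene_idx, kind="stable")
    bounds = np.searchsorted(index.gene_idx[order], np.arange(len(index.gene_ids) + 1))
    values = np.full((len(index.gene_ids), len(tables)), np.nan)
    for s, table in enumerate(tables):
        reordered = table.counts[order]
        for g in range(len(index.gene_ids)):
            lo, hi = bounds[g], bounds[g + 1]
            if hi > lo:
                values[g, s] = trimmed_mean(reordered[lo:hi], trim_fraction)
    data = pd.DataFrame(
        values, index=pd.Index(index.gene_ids, name="gene_id"),
        columns=[t.sample_id for t in tables],
    )
    return ExpressionMatrix(data=data, scale="raw")


def read_count_table_tsv(path, index: UniqueKmerIndex) -> KmerCountTable:
    """Read a count-table TSV back against the index it was counted with."""
    sample_id, reads_processed, digest = str(path), 0, ""
    counts = np.zeros(len(index), dtype=np.int64)
    lookup = {kmer: pos for pos, kmer in enumerate(index.kmer_strings())}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition(":")
                key, value = key.strip(), value.strip()
                if key == "sample":
                    sample_id = value
                elif key == "reads_processed":
                    reads_processed = int(value)
                elif key == "index":
                    digest = value
                continue
            fields = line.split("\t")
            if fields == ["gene_id", "kmer", "count"]:
                continue
            if len(fields) != 3:
                raise InputError(f"{path}: malformed count row at line {lineno}")
            gene, kmer, count = fields
            pos = lookup.get(kmer)
            if pos is None or index.gene_ids[int(index.gene_idx[pos])] != gene:
                raise InputError(
                    f"{path}: line {lineno}: k-mer/gene pair not in the index"
                )
            counts[pos] = int(count)
    if digest and digest != index.digest:
        raise ValidationError(f"{path}: count table was built against a different index")
    return KmerCountTable(sample_id=sample_id, index=index, counts=counts,
                          reads_processed=reads_processed)


def write_count_table_tsv(table: KmerCountTable, path) -> None:
    """Write nonzero counts as TSV (gene_id, kmer, count), sorted."""
    with open(path, "w") as fh:
        fh.write(f"# sample: {table.sample_id}\n")
        fh.write(f"# index: {table.index_digest}\n")
        fh.write(f"# reads_processed: {table.reads_processed}\n")
        fh.write("gene_id\tkmer\tcount\n")
        kmers = table.index.kmer_strings()
        rows = [
            (table.index.gene_ids[int(table.index.gene_idx[p])], kmers[p],
             int(table.counts[p]))
            for p in np.flatnonzero(table.counts)
        ]
        for gene, kmer, c in sorted(rows):
            fh.write(f"{gene}\t{kmer}\t{c}\n")
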