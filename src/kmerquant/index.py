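"""Gene-specific unique gapped k-mer index.

Expression is quantified from gapped k-mers that are *specific* for one
gene: every genomic window producing the (canonical) masked k-mer lies
entirely within that gene's annotated span, and nowhere else in the
genome.  Shared sequence between genes, or sequence duplicated in
intergenic regions, is thereby excluded automatically — no separate
repeat masking is needed.

The builder makes two passes over each chromosome in vectorized form:
a window census (masked-k-mer code per offset) and a containment
resolution that labels each window with the single gene fully containing
it (or marks it intergenic / ambiguous).  A k-mer enters the index iff
all its valid occurrences carry the same, unambiguous gene label.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError, ValidationError
from .mask import (
    GappedMask,
    decode_codes,
    encode_sequence,
    parse_mask,
    window_codes,
)

_INTERGENIC = -1
_AMBIGUOUS = -2


@dataclass(frozen=True)
class GeneInterval:
    """An annotated gene span, 0-based half-open, on a named chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class UniqueKmerIndex:
    """Mapping from canonical masked k-mer to its single containing gene.

    Entries are stored as parallel arrays sorted by k-mer code (which is
    lexicographic k-mer order): ``codes``, ``gene_idx`` (row into
    ``gene_ids``) and ``multiplicity`` (number of genomic occurrences,
    all inside the one gene).  ``gene_ids`` lists every annotated gene,
    including genes that ended up with zero unique k-mers.
    """

    mask: GappedMask
    canonical: bool
    gene_ids: list[str]
    codes: np.ndarray
    gene_idx: np.ndarray
    multiplicity: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def digest(self) -> str:
        """Stable identity of (mask, mode, entries) for cross-checking tables."""
        h = hashlib.sha256()
        h.update(self.mask.pattern.encode())
        h.update(b"canonical" if self.canonical else b"stranded")
        h.update(self.codes.tobytes())
        h.update(self.gene_idx.astype(np.int64).tobytes())
        return h.hexdigest()[:16]

    def kmer_strings(self) -> list[str]:
        return decode_codes(self.codes, self.mask.weight)

    def entries(self) -> Iterator[tuple[str, str, int]]:
        """Yield ``(kmer, gene_id, multiplicity)`` in sorted k-mer order."""
        for kmer, gi, m in zip(
            self.kmer_strings(), self.gene_idx, self.multiplicity
        ):
            yield kmer, self.gene_ids[int(gi)], int(m)

    def as_dict(self) -> dict[str, tuple[str, int]]:
        return {k: (g, m) for k, g, m in self.entries()}

    def kmers_per_gene(self) -> np.ndarray:
        """Number of indexed k-mers per gene, aligned with ``gene_ids``."""
        return np.bincount(self.gene_idx, minlength=len(self.gene_ids))


def _validate_annotation(
    genome: Mapping[str, str], annotation: Iterable[GeneInterval]
) -> list[GeneInterval]:
    genes = list(annotation)
    seen: set[str] = set()
    for g in genes:
        if g.chrom not in genome:
            raise InputError(
                f"gene {g.gene_id} references unknown chromosome {g.chrom!r}"
            )
        if g.end > len(genome[g.chrom]):
            raise InputError(
                f"gene {g.gene_id} extends past the end of {g.chrom} "
                f"({g.end} > {len(genome[g.chrom])})"
            )
        if g.gene_id in seen:
            raise InputError(f"duplicate gene_id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)
    return genes


def _chrom_census(
    seq: str, mask: GappedMask, canonical: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every full window of one chromosome."""
    fwd, rc, valid = window_codes(encode_sequence(seq), mask)
    codes = np.minimum(fwd, rc) if canonical else fwd
    return codes, valid


def enumerate_genome_kmers(
    genome: Mapping[str, str], mask: GappedMask, canonical: bool = True
) -> dict[str, list[tuple[str, int]]]:
    """Occurrence lists of every masked k-mer of a genome.

    Each full window of each chromosome is accounted for exactly once, at
    its forward-strand offset; in canonical mode the two strands collapse
    onto the canonical form.  Intended for inspection and small genomes —
    :func:`build_unique_index` never materializes this mapping.
    """
    if canonical and not mask.palindromic:
        raise ValidationError("canonical mode requires a palindromic mask")
    occurrences: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome.items():
        codes, valid = _chrom_census(seq, mask, canonical)
        offsets = np.flatnonzero(valid)
        for text, off in zip(decode_codes(codes[offsets], mask.weight), offsets):
            occurrences[text].append((chrom, int(off)))
    return dict(occurrences)


def build_unique_index(
    genome: Mapping[str, str],
    annotation: Iterable[GeneInterval],
    mask: GappedMask,
    canonical: bool = True,
    provenance: dict | None = None,
) -> UniqueKmerIndex:
    """Build the gene-specific unique k-mer index of a genome.

    A window belongs to a gene iff ``[offset, offset + w)`` lies entirely
    within the gene's span (introns included; the genome, not a
    transcriptome, is indexed).  A k-mer is indexed iff all its valid
    occurrences belong to one single gene; occurrences inside two
    overlapping genes disqualify it, as does any intergenic occurrence.
    Multiple in-gene copies are allowed and recorded as multiplicity.
    """
    if canonical and not mask.palindromic:
        raise ValidationError("canonical mode requires a palindromic mask")
    genes = _validate_annotation(genome, annotation)
    gene_ids = [g.gene_id for g in genes]
    w = mask.window

    all_codes: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    by_chrom: dict[str, list[tuple[int, GeneInterval]]] = defaultdict(list)
    for i, g in enumerate(genes):
        by_chrom[g.chrom].append((i, g))

    for chrom, seq in genome.items():
        codes, valid = _chrom_census(seq, mask, canonical)
        labels = np.full(codes.size, _INTERGENIC, dtype=np.int64)
        for gi, g in by_chrom.get(chrom, []):
            lo, hi = g.start, g.end - w  # inclusive window-offset span
            if hi < lo:
                continue
            hi = min(hi, codes.size - 1)
            seg = labels[lo : hi + 1]
            seg[seg != _INTERGENIC] = _AMBIGUOUS
            seg[seg == _INTERGENIC] = gi
        all_codes.append(codes[valid])
        all_labels.append(labels[valid])

    codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.int64)
    labels = np.concatenate(all_labels) if all_labels else np.empty(0, np.int64)

    if codes.size == 0:
        uniq = np.empty(0, np.int64)
        gidx = np.empty(0, np.int64)
        mult = np.empty(0, np.int64)
    else:
        order = np.argsort(codes, kind="stable")
        codes, labels = codes[order], labels[order]
        starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        lab_min = np.minimum.reduceat(labels, starts)
        lab_max = np.maximum.reduceat(labels, starts)
        sizes = np.diff(np.r_[starts, codes.size])
        keep = (lab_min == lab_max) & (lab_min >= 0)
        uniq = codes[starts[keep]]
        gidx = lab_min[keep]
        mult = sizes[keep]

    return UniqueKmerIndex(
        mask=mask,
        canonical=canonical,
        gene_ids=gene_ids,
        codes=uniq,
        gene_idx=gidx.astype(np.int64),
        multiplicity=mult.astype(np.int64),
        provenance=provenance or {},
    )


def index_stats(index: UniqueKmerIndex) -> pd.DataFrame:
    """Per-gene unique-k-mer counts and total genomic multiplicity.

    One row per annotated gene, zero counts included; genes without any
    unique k-mer are flagged unquantifiable.
    """
    n = index.kmers_per_gene()
    total = np.bincount(
        index.gene_idx, weights=index.multiplicity, minlength=len(index.gene_ids)
    ).astype(int)
    return pd.DataFrame(
        {
            "gene_id": index.gene_ids,
            "n_unique_kmers": n,
            "total_multiplicity": total,
            "quantifiable": n > 0,
        }
    )


# ---------------------------------------------------------------------------
# TSV serialization: sorted (kmer, gene_id, multiplicity) rows preceded by a
# '#'-prefixed header block recording mask, mode and provenance, so that
# builds are byte-reproducible and count tables can verify index identity.

def write_index_tsv(index: UniqueKmerIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mask: {index.mask.pattern}\n")
        fh.write(f"# canonical: {str(index.canonical).lower()}\n")
        fh.write(f"# genes: {','.join(index.gene_ids)}\n")
        for key in sorted(index.provenance):
            fh.write(f"# {key}: {index.provenance[key]}\n")
        fh.write("kmer\tgene_id\tmultiplicity\n")
        for kmer, gene, m in index.entries():
            fh.write(f"{kmer}\t{gene}\t{m}\n")


def read_index_tsv(path) -> UniqueKmerIndex:
    meta: dict[str, str] = {}
    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition(":")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if fields == ["kmer", "gene_id", "multiplicity"]:
                continue
            if len(fields) != 3:
                raise InputError(f"{path}: malformed index row at line {lineno}")
            rows.append((fields[0], fields[1], int(fields[2])))
    if "mask" not in meta or "genes" not in meta:
        raise InputError(f"{path}: missing index header block")
    mask = parse_mask(meta["mask"])
    gene_ids = meta["genes"].split(",") if meta["genes"] else []
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    k = mask.weight
    codes = np.empty(len(rows), dtype=np.int64)
    gidx = np.empty(len(rows), dtype=np.int64)
    mult = np.empty(len(rows), dtype=np.int64)
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, (kmer, gene, m) in enumerate(rows):
        if len(kmer) != k:
            raise InputError(f"{path}: k-mer {kmer!r} does not match mask weight {k}")
        code = 0
        for c in kmer:
            code = (code << 2) | enc[c]
        codes[i] = code
        gidx[i] = gene_pos[gene]
        mult[i] = m
    order = np.argsort(codes, kind="stable")
    provenance = {
        key: val
        for key, val in meta.items()
        if key not in {"mask", "canonical", "genes"}
    }
    return UniqueKmerIndex(
        mask=mask,
        canonical=meta.get("canonical", "true") == "true",
        gene_ids=gene_ids,
        codes=codes[order],
        gene_idx=gidx[order],
        multiplicity=mult[order],
        provenance=provenance,
    )
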