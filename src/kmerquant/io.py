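"""File formats: FASTA, FASTQ(.gz), GFF3, BED6, TSV matrices and tables.

Coordinate conventions: everything in memory is 0-based, half-open.
GFF3 is 1-based, closed on disk and converted losslessly on read/write;
BED is already 0-based half-open.  Matrix TSVs are tab-separated with a
``.`` decimal point, gene_id in the first column and ``NA`` for absent
genes, so reruns can be compared byte for byte.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .exceptions import InputError
from .index import GeneInterval


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


# -- FASTA -------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered name -> sequence mapping."""
    with _open_text(path) as fh:
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not genome:
        raise InputError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- FASTQ -------------------------------------------------------------------

def iter_fastq_seqs(path) -> Iterator[str]:
    """Stream read sequences (uppercased) from a plain or gzipped FASTQ.

    Qualities and titles are discarded.  A malformed record raises
    :class:`InputError` carrying the 1-based record number.
    """
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        record = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise InputError(
                    f"{path}: malformed FASTQ record {record + 1}: {exc}"
                ) from exc
            record += 1
            yield seq.upper()


def write_fastq(records: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write ``(title, sequence)`` pairs with a constant quality string."""
    with _open_text(path, "wt") as fh:
        for title, seq in records:
            fh.write(f"@{title}\n{seq}\n+\n{quality_char * len(seq)}\n")


# -- gene annotation ---------------------------------------------------------

def read_gff3_genes(path) -> list[GeneInterval]:
    """Extract ``gene`` features from GFF3 (ID attribute as gene_id).

    1-based closed coordinates are converted to 0-based half-open.
    """
    import gffutils

    with _open_text(path) as fh:
        text = fh.read()
    try:
        db = gffutils.create_db(
            text, dbfn=":memory:", from_string=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:
        raise InputError(f"{path}: GFF3 parse error: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneInterval(
                gene_id=gene_id, chrom=feat.seqid,
                start=feat.start - 1, end=feat.end,
                strand=feat.strand or ".",
            )
        )
    if not genes:
        raise InputError(f"{path}: no gene features found")
    return genes


def write_gff3(genes: Iterable[GeneInterval], path, source: str = "kmerquant") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{strand}\t.\tID={g.gene_id}\n"
            )


def read_bed6(path) -> list[GeneInterval]:
    """Read a 6-column BED (name column as gene_id); BED is already 0-based."""
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InputError(f"{path}: line {lineno}: expected 6 BED columns")
            try:
                genes.append(
                    GeneInterval(
                        gene_id=fields[3], chrom=fields[0],
                        start=int(fields[1]), end=int(fields[2]),
                        strand=fields[5],
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: {exc}") from exc
    if not genes:
        raise InputError(f"{path}: no BED records found")
    return genes


def write_bed6(genes: Iterable[GeneInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")


def read_annotation(path) -> list[GeneInterval]:
    """Dispatch on extension: .gff/.gff3 vs .bed."""
    name = str(path).removesuffix(".gz")
    if name.endswith((".gff", ".gff3")):
        return read_gff3_genes(path)
    if name.endswith(".bed"):
        return read_bed6(path)
    raise InputError(f"{path}: unrecognized annotation format (use .gff3 or .bed)")


# -- matrices and tables -----------------------------------------------------

def write_matrix_tsv(data: pd.DataFrame, path, meta: Mapping[str, str] | None = None,
                     float_format: str = "%.10g") -> None:
    """Gene x sample matrix as TSV; NaN written as NA; optional '#' header."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        data.to_csv(fh, sep="\t", na_rep="NA", float_format=float_format)


def read_matrix_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return pd.read_csv(_io.StringIO("".join(lines)), sep="\t", index_col=0,
                       na_values=["NA"])


def read_design_tsv(path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> sample_id-indexed group labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise InputError(f"{path}: design table needs sample_id and group columns")
    return pd.Series(
        df[cols["group"]].values, index=df[cols["sample_id"]].values, name="group"
    )
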