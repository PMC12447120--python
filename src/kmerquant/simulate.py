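"""Synthetic genomes, annotations and RNA-seq reads with known truth.

The generator emulates the statistical structure the pipeline assumes:
a small multi-gene genome (optionally carrying a verbatim repeated
segment shared between genes and an intergenic region, so that
uniqueness filtering is actually exercised), gene-level abundances with
a log-normal dynamic range, two conditions with a few replicates each,
log-normal replicate noise, per-sample depth multipliers, uniform read
start positions within gene spans, uniform strand choice, and i.i.d.
substitution errors.  Everything downstream of a seed is reproducible
byte for byte, and the truth tables store expected next to realized
read counts so failed recoveries are diagnosable.

Reads are drawn from genomic gene spans (no splicing), matching the
gene-span uniqueness criterion of the index.  Qualities are a constant
high Phred symbol since the counter ignores them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .index import GeneInterval

DEFAULT_WINDOW = 33  # span of the default spaced seed; minimum feature length
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
QUALITY_CHAR = "I"  # Phred+33 Q40


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment.

    ``genes`` has one row per gene (chrom, start, end, length, abundance,
    log2fc, in_repeat); ``samples`` one row per sample (group, depth,
    n_reads); ``expected``/``realized`` are gene x sample read-count
    tables filled as reads are drawn.
    """

    seed: int
    genes: pd.DataFrame
    samples: pd.DataFrame
    dispersion: float = 0.0
    read_length: int = 100
    error_rate: float = 0.0
    treatment_group: str = "treated"
    expected: pd.DataFrame = field(default=None, repr=False)
    realized: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.2:
            raise ValidationError("error_rate must be in [0, 0.2]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.expected is None:
            shape = (len(self.genes), len(self.samples))
            self.expected = pd.DataFrame(
                np.full(shape, np.nan), index=self.genes.index,
                columns=self.samples.index,
            )
        if self.realized is None:
            self.realized = self.expected.copy()

    def true_up_genes(self) -> pd.Index:
        return self.genes.index[self.genes["log2fc"] > 0]

    def write_tsv(self, genes_path, samples_path) -> None:
        genes = self.genes.copy()
        for sample in self.samples.index:
            genes[f"expected_{sample}"] = self.expected[sample]
            genes[f"realized_{sample}"] = self.realized[sample]
        header = (
            f"# seed: {self.seed}\n# dispersion: {self.dispersion}\n"
            f"# read_length: {self.read_length}\n# error_rate: {self.error_rate}\n"
            f"# treatment_group: {self.treatment_group}\n"
        )
        with open(genes_path, "w") as fh:
            fh.write(header)
            genes.to_csv(fh, sep="\t", na_rep="NA")
        with open(samples_path, "w") as fh:
            fh.write(header)
            self.samples.to_csv(fh, sep="\t")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode()


def simulate_genome(
    n_genes: int,
    gene_length: int = 500,
    intergenic_length: int = 200,
    repeat_spec: tuple[int, int] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
    window: int = DEFAULT_WINDOW,
) -> tuple[dict[str, str], list[GeneInterval], SyntheticTruth]:
    """One-chromosome random genome with evenly spaced genes.

    ``repeat_spec = (n_copies, repeat_length)`` plants a verbatim shared
    segment inside the first ``n_copies`` genes and once in the leading
    intergenic region, guaranteeing that non-unique k-mers exist.
    Returns the genome, the annotation, and a truth skeleton (abundances
    and effects unset) that :func:`make_experiment` fills in.
    """
    if gene_length < window or intergenic_length < window:
        raise ValidationError(
            f"gene and intergenic lengths must be >= the mask window ({window})"
        )
    if repeat_spec is not None:
        n_copies, repeat_length = repeat_spec
        if repeat_length > gene_length or repeat_length > intergenic_length:
            raise ValidationError(
                "repeat_length must fit inside genes and intergenic spacers"
            )
        if n_copies > 0 and n_genes < max(2, n_copies):
            raise ValidationError("repeat_spec needs at least two genes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    total = intergenic_length + n_genes * (gene_length + intergenic_length)
    codes = _random_sequence(rng, total)

    annotation: list[GeneInterval] = []
    rows = []
    for i in range(n_genes):
        start = intergenic_length + i * (gene_length + intergenic_length)
        end = start + gene_length
        gene_id = f"gene{i + 1:04d}"
        annotation.append(GeneInterval(gene_id, chrom, start, end, "+"))
        rows.append((gene_id, chrom, start, end, gene_length))

    in_repeat = np.zeros(n_genes, dtype=bool)
    if repeat_spec is not None and repeat_spec[0] > 0:
        n_copies, repeat_length = repeat_spec
        segment = _random_sequence(rng, repeat_length)
        offset = (gene_length - repeat_length) // 2
        for i in range(min(n_copies, n_genes)):
            start = annotation[i].start + offset
            codes[start : start + repeat_length] = segment
            in_repeat[i] = True
        ig_off = (intergenic_length - repeat_length) // 2
        codes[ig_off : ig_off + repeat_length] = segment  # intergenic copy

    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "length"]
    ).set_index("gene_id")
    genes["abundance"] = np.nan
    genes["log2fc"] = 0.0
    genes["in_repeat"] = in_repeat
    samples = pd.DataFrame(columns=["group", "depth", "n_reads"])
    truth = SyntheticTruth(seed=int(seed), genes=genes, samples=samples)
    return {chrom: _to_str(codes)}, annotation, truth


def simulate_reads(
    genome: dict[str, str],
    annotation: list[GeneInterval],
    truth: SyntheticTruth,
    sample_id: str,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Draw one sample's reads; returns ``(title, sequence)`` pairs.

    Per gene the expected read count is ``abundance * 2**log2fc *
    depth`` (the effect applies only in the treatment group), perturbed
    by a multiplicative log-normal replicate factor of sd ``dispersion``
    (log2 units) and rounded.  Also records the expected and realized
    counts into the truth tables.
    """
    if sample_id not in truth.samples.index:
        raise ValidationError(f"sample {sample_id!r} not present in the truth table")
    sample = truth.samples.loc[sample_id]
    sample_pos = int(truth.samples.index.get_loc(sample_id))
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0x5EED, sample_pos])
    )
    length = truth.read_length
    treated = sample["group"] == truth.treatment_group

    enc = {}
    lut = np.full(256, 0, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        lut[b] = v
    for name, seq in genome.items():
        enc[name] = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]

    gene_rows = truth.genes
    expected = gene_rows["abundance"].to_numpy(float) * float(sample["depth"])
    if treated:
        expected = expected * 2.0 ** gene_rows["log2fc"].to_numpy(float)
    noise = 2.0 ** rng.normal(0.0, truth.dispersion, size=expected.size)
    realized = np.rint(expected * noise).astype(int)
    truth.expected[sample_id] = expected
    truth.realized[sample_id] = realized.astype(float)

    records: list[tuple[str, str]] = []
    read_no = 0
    for (gene_id, row), n_reads in zip(gene_rows.iterrows(), realized):
        if n_reads <= 0:
            continue
        if length > row["length"]:
            raise ValidationError(
                f"read_length {length} exceeds gene {gene_id} length {row['length']}"
            )
        chrom_codes = enc[row["chrom"]]
        starts = rng.integers(row["start"], row["end"] - length + 1, size=n_reads)
        reads = chrom_codes[starts[:, None] + np.arange(length)]
        reverse = rng.random(n_reads) < 0.5
        reads[reverse] = 3 - reads[reverse, ::-1]
        if truth.error_rate > 0:
            err = rng.random(reads.shape) < truth.error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            reads[err] = (reads[err] + shift) % 4
        # one bulk decode per gene: newline-join rows, then split
        letters = np.hstack(
            [_BASES[reads], np.full((n_reads, 1), ord("\n"), dtype=np.uint8)]
        )
        seqs = bytes(letters).decode().split()
        for seq in seqs:
            read_no += 1
            records.append((f"{sample_id}:{gene_id}:{read_no}", seq))
    truth.samples.loc[sample_id, "n_reads"] = len(records)
    return records


@dataclass
class SyntheticExperiment:
    """A complete simulated dataset: genome, annotation, truth, reads."""

    genome: dict[str, str]
    annotation: list[GeneInterval]
    truth: SyntheticTruth
    _reads: dict[str, list[tuple[str, str]]] = field(default_factory=dict, repr=False)

    def reads(self, sample_id: str) -> list[tuple[str, str]]:
        if sample_id not in self._reads:
            self._reads[sample_id] = simulate_reads(
                self.genome, self.annotation, self.truth, sample_id
            )
        return self._reads[sample_id]

    def read_seqs(self, sample_id: str) -> list[str]:
        return [seq for _, seq in self.reads(sample_id)]

    def write(self, outdir, gzip_fastq: bool = True) -> dict[str, str]:
        """Write FASTA, GFF3, per-sample FASTQ(.gz), design and truth TSVs."""
        import os

        from .io import write_fasta, write_fastq, write_gff3

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fasta"),
            "annotation": os.path.join(outdir, "genes.gff3"),
            "design": os.path.join(outdir, "design.tsv"),
            "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
            "truth_samples": os.path.join(outdir, "truth_samples.tsv"),
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.annotation, paths["annotation"])
        ext = ".fastq.gz" if gzip_fastq else ".fastq"
        for sample_id in self.truth.samples.index:
            p = os.path.join(outdir, f"{sample_id}{ext}")
            write_fastq(self.reads(sample_id), p, quality_char=QUALITY_CHAR)
            paths[f"fastq:{sample_id}"] = p
        with open(paths["design"], "w") as fh:
            fh.write("sample_id\tgroup\n")
            for s, row in self.truth.samples.iterrows():
                fh.write(f"{s}\t{row['group']}\n")
        self.truth.write_tsv(paths["truth_genes"], paths["truth_samples"])
        return paths


def make_experiment(
    n_genes: int = 1000,
    replicates: int = 3,
    groups: tuple[str, str] = ("control", "treated"),
    de_fraction: float = 0.1,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.2,
    depth_range: tuple[float, float] = (0.5, 2.0),
    gene_length: int = 500,
    intergenic_length: int = 200,
    repeat_spec: tuple[int, int] | None = None,
    read_length: int = 100,
    error_rate: float = 0.005,
    mean_log2_abundance: float = 6.0,
    sd_log2_abundance: float = 1.0,
    seed: int = 0,
) -> SyntheticExperiment:
    """Full two-condition experiment with designated truly upregulated genes.

    Defaults mirror the analysis' target design: two conditions with
    three replicates each, 10% truly upregulated genes at log2FC 2,
    moderate replicate dispersion (sd 0.2 on log2 counts, about a
    15% coefficient of variation between replicates), per-sample
    depth multipliers spanning a 4-fold range to exercise normalization,
    and a mild 0.5% substitution error rate.  ``abundance`` is the
    expected read count of a gene at depth multiplier 1, drawn log-
    normally (median ``2**mean_log2_abundance`` = 64 reads, giving roughly 13-fold
    read coverage of a 500 bp gene at depth 1).
    """
    if not 0 <= de_fraction <= 1:
        raise ValidationError("de_fraction must be in [0, 1]")
    genome, annotation, truth = simulate_genome(
        n_genes, gene_length=gene_length, intergenic_length=intergenic_length,
        repeat_spec=repeat_spec, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE9]))
    truth.genes["abundance"] = 2.0 ** rng.normal(
        mean_log2_abundance, sd_log2_abundance, size=n_genes
    )
    n_up = math.ceil(de_fraction * n_genes)
    up = rng.choice(n_genes, size=n_up, replace=False)
    log2fc = np.zeros(n_genes)
    log2fc[up] = effect_log2fc
    truth.genes["log2fc"] = log2fc

    sample_rows = []
    for group in groups:
        for r in range(1, replicates + 1):
            sample_rows.append((f"{group}_{r}", group))
    depths = rng.uniform(depth_range[0], depth_range[1], size=len(sample_rows))
    truth.samples = pd.DataFrame(
        {
            "group": [g for _, g in sample_rows],
            "depth": depths,
            "n_reads": 0,
        },
        index=pd.Index([s for s, _ in sample_rows], name="sample_id"),
    )
    truth.dispersion = float(dispersion)
    truth.read_length = int(read_length)
    truth.error_rate = float(error_rate)
    truth.treatment_group = groups[1]
    truth.expected = pd.DataFrame(
        np.full((n_genes, len(sample_rows)), np.nan),
        index=truth.genes.index, columns=truth.samples.index,
    )
    truth.realized = truth.expected.copy()
    return SyntheticExperiment(genome=genome, annotation=annotation, truth=truth)
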