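"""End-to-end orchestration: simulate -> index -> count -> quantify ->
normalize -> differential expression.

Every tunable constant of the analysis lives in :class:`PipelineConfig`
(stage code contains no magic numbers); its defaults are the analysis'
standard constants of the analysis — the spaced seed ``######_##_###___#___###_##_######``,
the 0.50–0.98 quantile range, fold-change threshold 1.61 and FDR 0.05.
Each stage writes its output with a metadata header (config digest,
input digests), and a JSON run manifest records what was produced;
outputs contain no timestamps, so a rerun with identical inputs and
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time
from dataclasses import asdict, dataclass, replace

import yaml

from . import diffexpr as de
from . import normalize as norm
from .exceptions import KmerQuantError, ValidationError
from .index import build_unique_index, index_stats, read_index_tsv, write_index_tsv
from .io import (
    file_digest,
    read_annotation,
    read_design_tsv,
    read_fasta,
    write_matrix_tsv,
)
from .mask import DEFAULT_MASK_PATTERN, parse_mask
from .quantify import (
    ExpressionMatrix,
    count_sample,
    read_count_table_tsv,
    summarize_expression,
    write_count_table_tsv,
)

logger = logging.getLogger("kmerquant")


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis constants in one place.

    Defaults are the standard analysis settings: the k=23/w=33
    spaced seed, canonical (strand-agnostic) counting, trimmed-mean
    summarization (5% per tail), quantile-offset normalization on the
    0.50–0.98 grid with pseudocount 0.5 and a least-squares intercept
    fit, and up-calls at fold change > 1.61 with BH FDR < 0.05.
    """

    mask: str = DEFAULT_MASK_PATTERN
    canonical: bool = True
    trim_fraction: float = 0.05
    q_lo: float = 0.5
    q_hi: float = 0.98
    q_step: float = 0.01
    pseudocount: float = 0.5
    offset_fit: str = "least-squares"  # or "median"
    fc_threshold: float = 1.61
    alpha: float = 0.05
    two_sided: bool = True
    contrast: tuple[str, str] = ("control", "treated")
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "contrast" in data:
            data["contrast"] = tuple(data["contrast"])
        cfg = cls(**data)
        return replace(cfg, **overrides) if overrides else cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["contrast"] = list(data["contrast"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


class _Stage:
    """Context manager logging per-stage timing and naming failures."""

    def __init__(self, name: str, manifest: dict):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc is None:
            self.manifest["stages"][self.name] = "complete"
            logger.info("stage %s: done in %.1fs", self.name, elapsed)
            return False
        self.manifest["stages"][self.name] = "failed"
        if isinstance(exc, KmerQuantError):
            raise KmerQuantError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(
    config: PipelineConfig,
    genome_path,
    annotation_path,
    fastq_paths: dict[str, str],
    design_path,
    outdir,
) -> de.DEResults:
    """Run index -> count -> quantify -> normalize -> de on files.

    ``fastq_paths`` maps sample_id to a FASTQ(.gz) path; the design TSV
    assigns each sample to a group and ``config.contrast`` names the
    (reference, treatment) pair.  All intermediate artifacts are written
    under ``outdir`` along with a JSON run manifest.
    """
    os.makedirs(outdir, exist_ok=True)
    mask = parse_mask(config.mask)
    manifest: dict = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "inputs": {
            "genome": file_digest(genome_path),
            "annotation": file_digest(annotation_path),
            **{f"fastq:{s}": file_digest(p) for s, p in sorted(fastq_paths.items())},
        },
        "stages": {},
        "outputs": {},
    }
    meta = {"config": config.digest()}

    def out(name: str) -> str:
        manifest["outputs"][name] = name  # paths relative to the run directory
        return os.path.join(outdir, name)

    try:
        with _Stage("index", manifest):
            genome = read_fasta(genome_path)
            annotation = read_annotation(annotation_path)
            index = build_unique_index(
                genome, annotation, mask, canonical=config.canonical,
                provenance={
                    "genome_digest": manifest["inputs"]["genome"],
                    "annotation_digest": manifest["inputs"]["annotation"],
                },
            )
            write_index_tsv(index, out("unique_kmers.tsv"))
            write_matrix_tsv(
                index_stats(index).set_index("gene_id"),
                out("index_stats.tsv"), meta=meta,
            )

        with _Stage("count", manifest):
            tables = []
            for sample_id in sorted(fastq_paths):
                table = count_sample(fastq_paths[sample_id], index,
                                     sample_id=sample_id)
                logger.info(
                    "  %s: %d reads, %d windows matched",
                    sample_id, table.reads_processed, table.windows_matched,
                )
                write_count_table_tsv(table, out(f"counts_{sample_id}.tsv"))
                tables.append(table)

        with _Stage("quantify", manifest):
            raw = summarize_expression(tables, index, config.trim_fraction)
            write_matrix_tsv(raw.data, out("expression_raw.tsv"), meta=meta)

        with _Stage("normalize", manifest):
            grid = norm.make_quantile_grid(config.q_lo, config.q_hi, config.q_step)
            model = norm.QuantileOffsetNormalization(
                raw, grid=grid, pseudocount=config.pseudocount
            ).fit(method=config.offset_fit)
            model.to_json(out("normalization.json"))
            normalized = model.apply(raw)
            write_matrix_tsv(normalized.data, out("expression_normalized.tsv"),
                             meta=meta)

        with _Stage("de", manifest):
            groups = read_design_tsv(design_path)
            design = de.ExperimentDesign.from_series(groups, config.contrast)
            results = de.DifferentialExpression(normalized, design).fit(
                de.DEConfig(fc_threshold=config.fc_threshold, alpha=config.alpha,
                            two_sided=config.two_sided)
            )
            results.to_tsv(out("de_table.tsv"), meta=meta)
    finally:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    return results


def quantify_from_files(index_path, count_paths, trim_fraction, out_path,
                        meta=None) -> ExpressionMatrix:
    """Stage entry point: count TSVs + index TSV -> raw expression TSV."""
    index = read_index_tsv(index_path)
    tables = [read_count_table_tsv(p, index) for p in count_paths]
    raw = summarize_expression(tables, index, trim_fraction)
    write_matrix_tsv(raw.data, out_path, meta=meta or {})
    return raw


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
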