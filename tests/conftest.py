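"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every quantity by the most literal route possible
(pure-Python string scans, closed forms, step-up loops) and never touch
the package's vectorized code paths, so agreement is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from kmerquant import GeneInterval

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(seq))


def oracle_apply_mask(window: str, pattern: str) -> str:
    return "".join(c for c, m in zip(window, pattern) if m == "#")


def oracle_extract(seq: str, pattern: str, canonical: bool) -> list[tuple[str, int]]:
    """Brute-force window scan: one candidate per offset, N-windows skipped."""
    w = len(pattern)
    out = []
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        kmer = oracle_apply_mask(window, pattern)
        if any(c not in "ACGT" for c in kmer):
            continue
        if canonical:
            kmer = min(kmer, oracle_apply_mask(rc(window), pattern))
        out.append((kmer, off))
    return out


def oracle_occurrences(genome: dict[str, str], pattern: str, canonical: bool
                       ) -> dict[str, list[tuple[str, int]]]:
    occ: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for kmer, off in oracle_extract(seq, pattern, canonical):
            occ.setdefault(kmer, []).append((chrom, off))
    return occ


def oracle_unique_index(genome: dict[str, str], annotation: list[GeneInterval],
                        pattern: str, canonical: bool) -> dict[str, tuple[str, int]]:
    """Exhaustive enumeration + interval-containment filter."""
    w = len(pattern)
    occ = oracle_occurrences(genome, pattern, canonical)
    index: dict[str, tuple[str, int]] = {}
    for kmer, places in occ.items():
        genes_hit = set()
        ok = True
        for chrom, off in places:
            containing = [
                g.gene_id
                for g in annotation
                if g.chrom == chrom and g.start <= off and off + w <= g.end
            ]
            if len(containing) != 1:
                ok = False
                break
            genes_hit.add(containing[0])
        if ok and len(genes_hit) == 1:
            index[kmer] = (genes_hit.pop(), len(places))
    return index


def oracle_trimmed_mean(values, frac: float) -> float:
    vals = sorted(values)
    cut = math.floor(frac * len(vals))
    kept = vals[cut : len(vals) - cut]
    return sum(kept) / len(kept)


def oracle_welch(a, b) -> tuple[float, float, float]:
    """Hand-evaluated Welch formulas; p via the regularized t CDF."""
    from scipy.special import stdtr

    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return t, df, p


def oracle_bh(p_values) -> list[float]:
    """Literal step-up definition: min over j >= rank of m * p_(j) / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = running
    return adjusted


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def mask33():
    from kmerquant import default_mask

    return default_mask()


@pytest.fixture(scope="session")
def tiny_mask():
    from kmerquant import parse_mask

    return parse_mask("#_#")


@pytest.fixture(scope="session")
def toy_dataset():
    """Small genome with shared repeated sequence, plus its annotation.

    Two of the four genes share a verbatim 60 bp segment that also
    occurs intergenically, so uniqueness filtering has real work to do.
    """
    rng = np.random.default_rng(20240917)
    gene_len, spacer_len = 160, 80
    repeat = random_genome(rng, 60)
    pieces, annotation, pos = [], [], 0

    def add(seq):
        nonlocal pos
        pieces.append(seq)
        pos += len(seq)

    add(random_genome(rng, 10) + repeat + random_genome(rng, 10))  # intergenic copy
    for i in range(4):
        start = pos
        if i < 2:
            core = random_genome(rng, gene_len - 60 - 20)
            add(random_genome(rng, 10) + repeat + random_genome(rng, 10) + core)
        else:
            add(random_genome(rng, gene_len))
        annotation.append(GeneInterval(f"g{i + 1}", "chrA", start, pos, "+"))
        add(random_genome(rng, spacer_len))
    return {"chrA": "".join(pieces)}, annotation


@pytest.fixture(scope="session")
def small_experiment():
    """One modest simulated experiment shared across tests (read-only)."""
    from kmerquant import make_experiment

    return make_experiment(
        n_genes=40, gene_length=300, intergenic_length=120,
        repeat_spec=(3, 80), de_fraction=0.2, seed=424242,
    )
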