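"""Gapped-mask (spaced-seed) parsing and masked k-mer extraction.

A gapped k-mer is sampled from a window of length ``w`` at the ``k``
positions a mask marks as *considered* (``#``); *ignored* positions
(``_``) are skipped, which makes the k-mer tolerant to mismatches there.
The default mask used throughout the pipeline is::

    ######_##_###___#___###_##_######      (w = 33, k = 23)

which is palindromic (equal to its own reversal), so the reverse
complement of a masked k-mer is itself a masked k-mer of the reverse
complement strand and canonical (strand-agnostic) counting is well
defined.

Internally k-mers are 2-bit encoded into ``int64`` codes (A=0, C=1, G=2,
T=3); because the base order matches the alphabetical order, sorting by
code equals sorting k-mer strings lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import ContractError, MaskFormatError, ValidationError

CONSIDERED = "#"
IGNORED = "_"

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

# byte -> 2-bit code; anything that is not ACGT (either case) maps to 255
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


class MaskedKmer(NamedTuple):
    """A masked k-mer and the 0-based offset of its source window."""

    text: str
    offset: int


@dataclass(frozen=True)
class GappedMask:
    """A validated spaced-seed pattern.

    Attributes
    ----------
    pattern:
        The mask string over ``{#, _}``.
    positions:
        0-based window offsets of the considered positions, ascending.
    """

    pattern: str
    positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        pos = tuple(i for i, c in enumerate(self.pattern) if c == CONSIDERED)
        object.__setattr__(self, "positions", pos)

    @property
    def window(self) -> int:
        """Window length ``w`` (total span of the mask)."""
        return len(self.pattern)

    @property
    def weight(self) -> int:
        """Mask weight ``k`` (number of considered positions)."""
        return len(self.positions)

    @property
    def palindromic(self) -> bool:
        return self.pattern == self.pattern[::-1]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.pattern


#: The pipeline's default spaced seed (palindromic, k=23, w=33).
DEFAULT_MASK_PATTERN = "######_##_###___#___###_##_######"


def parse_mask(pattern: str) -> GappedMask:
    """Parse and validate a mask pattern string.

    Raises
    ------
    MaskFormatError
        If the pattern is empty, contains characters other than ``#``/``_``,
        or starts/ends with an ignored position (such a mask is equivalent
        to a shorter one and is rejected rather than silently trimmed).
    """
    if not pattern:
        raise MaskFormatError("mask pattern is empty")
    illegal = set(pattern) - {CONSIDERED, IGNORED}
    if illegal:
        raise MaskFormatError(
            f"mask pattern contains illegal characters {sorted(illegal)!r}; "
            f"only {CONSIDERED!r} (considered) and {IGNORED!r} (ignored) are allowed"
        )
    if pattern[0] == IGNORED or pattern[-1] == IGNORED:
        raise MaskFormatError(
            "mask must begin and end with a considered position "
            "(an equivalent shorter mask exists otherwise)"
        )
    return GappedMask(pattern)


def default_mask() -> GappedMask:
    return parse_mask(DEFAULT_MASK_PATTERN)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def apply_mask(window: str, mask: GappedMask) -> str:
    """Concatenate the window's bases at the mask's considered positions."""
    if len(window) != mask.window:
        raise ContractError(
            f"window length {len(window)} != mask window {mask.window}"
        )
    return "".join(window[i] for i in mask.positions)


def canonical_form(window: str, mask: GappedMask) -> str:
    """Strand-canonical masked k-mer of a window.

    Returns the lexicographically smaller of the forward masked k-mer and
    the masked k-mer of the reverse-complemented window.  Only defined for
    palindromic masks: for those the latter equals the reverse complement
    of the former, so canonicalization commutes with masking.
    """
    if not mask.palindromic:
        raise ValidationError(
            "canonical masked k-mers are only defined for palindromic masks"
        )
    fwd = apply_mask(window, mask)
    rev = apply_mask(reverse_complement(window), mask)
    return min(fwd, rev)


def encode_sequence(seq: str | bytes) -> np.ndarray:
    """2-bit encode a nucleotide string; non-ACGT bases become 255."""
    if isinstance(seq, str):
        seq = seq.encode("ascii", errors="replace")
    return _BASE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def window_codes(
    encoded: np.ndarray, mask: GappedMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized masked-k-mer codes for every full window of a sequence.

    Parameters
    ----------
    encoded:
        Output of :func:`encode_sequence`.

    Returns
    -------
    (fwd, rc, valid):
        ``fwd[i]`` is the int64 code of the forward masked k-mer of the
        window starting at offset ``i``; ``rc[i]`` the code of its reverse
        complement; ``valid[i]`` is False when a considered position holds
        a non-ACGT base.  All arrays have length ``max(0, n - w + 1)``.
    """
    w, k = mask.window, mask.weight
    n_win = encoded.size - w + 1
    if n_win <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), np.empty(0, dtype=bool)
    e = (encoded & 3).astype(np.int64)
    bad = encoded == 255
    fwd = np.zeros(n_win, dtype=np.int64)
    rc = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    tmp = np.empty(n_win, dtype=np.int64)
    for j, p in enumerate(mask.positions):
        b = e[p : p + n_win]
        valid &= ~bad[p : p + n_win]
        np.left_shift(b, 2 * (k - 1 - j), out=tmp)
        fwd += tmp
        np.subtract(3, b, out=tmp)
        tmp <<= 2 * j
        rc += tmp
    return fwd, rc, valid


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """Decode int64 k-mer codes back to strings (inverse of the encoding)."""
    codes = np.asarray(codes, dtype=np.int64)
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    digits = (codes[:, None] >> shifts) & 3
    letters = np.frombuffer("ACGT".encode(), dtype=np.uint8)[digits]
    return [bytes(row).decode() for row in letters]


def extract_kmers(
    sequence: str, mask: GappedMask, canonical: bool = True
) -> list[MaskedKmer]:
    """All masked k-mers of a sequence, one candidate per window offset.

    Windows with a non-ACGT base at a considered position are skipped
    entirely.  With ``canonical=True`` (palindromic masks only) each
    emitted k-mer is the lexicographic minimum of the forward and
    reverse-complement forms.  A sequence shorter than the window yields
    an empty list.
    """
    if canonical and not mask.palindromic:
        raise ValidationError(
            "canonical extraction requires a palindromic mask"
        )
    enc = encode_sequence(sequence)
    fwd, rc, valid = window_codes(enc, mask)
    codes = np.minimum(fwd, rc) if canonical else fwd
    offsets = np.flatnonzero(valid)
    texts = decode_codes(codes[offsets], mask.weight)
    return [MaskedKmer(t, int(o)) for t, o in zip(texts, offsets)]
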