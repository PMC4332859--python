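"""Primitive operations on DNA tag sequences.

A *tag* (barcode) is a short word over the alphabet {A, C, G, T}, written
5'->3'.  Throughout the package tags are plain Python strings in canonical
uppercase form; :func:`canonicalize` is the single entry point that upcases
and validates raw input.  Numeric routines use the base-4 integer encoding
A=0, C=1, G=2, T=3 (most-significant digit first), which identifies the set
of length-n tags with the integers [0, 4**n).
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset(ALPHABET)


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A, C, G, T}."""


def canonicalize(seq: str) -> str:
    """Upcase ``seq`` and verify it is a non-empty word over {A, C, G, T}.

    IUPAC ambiguity codes (including N) are rejected: a tag is a concrete
    synthesizable oligo, not a sequence pattern.
    """
    s = seq.strip().upper()
    if not s:
        raise InvalidAlphabetError("empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise InvalidAlphabetError(
            f"invalid character(s) {sorted(bad)} in sequence {seq!r}; "
            "only A, C, G, T are allowed"
        )
    return s


def gc_content(seq: str) -> float:
    """GC content of ``seq`` as a percentage: 100 * (#G + #C) / n."""
    s = canonicalize(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def gc_count(seq: str) -> int:
    """Number of G or C bases in ``seq``."""
    s = canonicalize(seq)
    return s.count("G") + s.count("C")


def longest_run(seq: str) -> int:
    """Length of the longest homopolymer run (maximal substring of one base).

    Long runs of a single base destabilize the duplex and inflate
    sequencing error, so tag designs cap this quantity.
    """
    s = canonicalize(seq)
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, both strands written 5'->3'.

    Involutive: ``reverse_complement(reverse_complement(u)) == u``.
    """
    return canonicalize(seq).translate(_COMPLEMENT)[::-1]


def is_self_complementary(seq: str) -> bool:
    """True iff ``seq`` equals its own reverse complement.

    Such a palindromic tag can hybridize with copies of itself; valid tag
    sets exclude them.  Odd-length words are never self-complementary.
    """
    s = canonicalize(seq)
    return s == reverse_complement(s)


# ---------------------------------------------------------------------------
# base-4 codec between words and integers


def sequence_to_index(seq: str) -> int:
    """Base-4 positional encoding of ``seq`` (A=0, C=1, G=2, T=3, MSD first)."""
    s = canonicalize(seq)
    idx = 0
    for ch in s:
        idx = idx * 4 + _CODE[ch]
    return idx


def index_to_sequence(index: int, n: int) -> str:
    """Inverse of :func:`sequence_to_index` for length-``n`` words."""
    if not 0 <= index < 4**n:
        raise ValueError(f"index {index} out of range for length {n} (must be in [0, 4^{n}))")
    digits = []
    for _ in range(n):
        digits.append(ALPHABET[index & 3])
        index >>= 2
    return "".join(reversed(digits))


# ---------------------------------------------------------------------------
# numpy code-array conversions (used by the GA engine)


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 code vector (A=0, C=1, G=2, T=3)."""
    s = canonicalize(seq)
    return np.array([_CODE[c] for c in s], dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    """uint8 code vector -> sequence string."""
    return "".join(ALPHABET[c] for c in np.asarray(codes, dtype=np.uint8))
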