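"""Low-level nucleotide utilities shared across the package.

Coordinates are 0-based, half-open everywhere. Sequences are plain upper-case
strings over the IUPAC nucleotide alphabet (ACGT, the eleven ambiguity codes,
and N).
"""

from __future__ import annotations

from typing import Iterator

BASES = "ACGT"

#: IUPAC one-letter code -> set of concrete bases it denotes.
IUPAC_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_SET.items() if k != "N"}
SET_TO_IUPAC[frozenset("ACGT")] = "N"

IUPAC_ALPHABET = frozenset(IUPAC_TO_SET)
AMBIGUITY_CODES = frozenset(IUPAC_ALPHABET - frozenset("ACGTN"))

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases) -> str:
    """Standard IUPAC ambiguity code for a non-empty set of concrete bases.

    A singleton set maps to the base itself; the full set maps to N.
    """
    s = frozenset(bases)
    if not s:
        raise ValueError("empty base set has no IUPAC code")
    bad = s - frozenset(BASES)
    if bad:
        raise ValueError(f"invalid base(s) for IUPAC coding: {sorted(bad)}")
    return SET_TO_IUPAC[s]


def iupac_set(code: str) -> frozenset[str]:
    """Concrete bases denoted by one IUPAC symbol."""
    try:
        return IUPAC_TO_SET[code]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def is_compatible(a: str, b: str) -> bool:
    """True if the base sets of two IUPAC symbols intersect."""
    return bool(iupac_set(a) & iupac_set(b))


def maximal_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal homopolymer runs as (start, length, base), covering the sequence."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i, seq[i]))
        i = j
    return runs


def run_at(seq: str, pos: int) -> tuple[int, int, str]:
    """The maximal run containing ``pos``: (start, length, base)."""
    base = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos + 1
    while j < len(seq) and seq[j] == base:
        j += 1
    return (i, j - i, base)


def random_sequence(rng, length: int, gc_fraction: float = 0.5) -> str:
    """Random DNA with the requested expected GC content."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[i] for i in idx)


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Index of every k-mer to its start positions."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def wrap_slice(seq: str, start: int, end: int) -> str:
    """Circular slice: ``end`` may exceed len(seq) to wrap past the origin."""
    n = len(seq)
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def chunk_iter(seq: str, width: int = 70) -> Iterator[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]
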