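"""Quadripartite plastome structure: IR detection and normalization.

A plastome is modelled as a circle carrying a large and a small single-copy
region (LSC, SSC) separated by a pair of near-identical inverted repeats
(IRb, IRa). Detection finds the maximal inverted-repeat pair by k-mer
seeding on the antidiagonal and mismatch-budgeted boundary extension;
canonicalization rotates the circle so position 0 is the LSC start and the
region order along the sequence is LSC - IRb - SSC - IRa. Because the SSC
sits between two repeats, its orientation is a free parameter of any
assembly ("flip-flop"); `normalize_ssc_orientation` resolves it against a
reference.

Intervals are 0-based half-open; an interval's end may exceed the sequence
length to denote wrapping past the origin of the circle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import edlib

from ._seq import (
    IUPAC_ALPHABET,
    complement,
    revcomp,
    wrap_slice,
)
from .errors import ConfigError, NoQuadripartiteStructureError

_SEED_K = 21  # seed k-mer length for IR detection


@dataclass(frozen=True)
class QuadripartitePartition:
    """Coordinates of the four plastome regions on one rotation of the circle.

    ``ir_identity`` is the fraction of matching columns between IRb and the
    reverse complement of IRa (1.0 for a perfect repeat).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_identity: float = 1.0

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def __post_init__(self):
        if self.irb[1] - self.irb[0] != self.ira[1] - self.ira[0]:
            raise ConfigError("IRb and IRa must have equal lengths")
        if any(e <= s for s, e in (self.lsc, self.irb, self.ssc, self.ira)):
            raise ConfigError("region intervals must be non-empty")


@dataclass
class PlastomeSequence:
    """A plastome (or assembly of one) with optional structural annotation."""

    id: str
    sequence: str
    circular: bool = True
    partition: QuadripartitePartition | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ConfigError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}")

    def __len__(self):
        return len(self.sequence)


def partition_report(partition: QuadripartitePartition) -> dict[str, int]:
    """Region-length summary: lsc_len, ssc_len, ir_len and their total."""
    return {
        "lsc_len": partition.lsc_len,
        "ssc_len": partition.ssc_len,
        "ir_len": partition.ir_len,
        "total_len": partition.total_len,
    }


def _antidiagonal_hits(s2: str, n: int, k: int) -> dict[int, list[tuple[int, int]]]:
    """k-mer seed matches between the circle and its reverse complement.

    Returns antidiagonal d = i + j -> (i, j) pairs, where
    s2[i:i+k] == revcomp(s2[j:j+k]), i in [0, n), i < j <= i + n - k.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(s2) - k + 1):
        index[s2[j : j + k]].append(j)
    diags: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for i in range(n):
        rc = revcomp(s2[i : i + k])
        for j in index.get(rc, ()):
            if i < j <= i + n - k:
                diags[i + j].append((i, j))
    return diags


def detect_inverted_repeats(seq: PlastomeSequence | str, min_ir_len: int = 1000,
                            max_mismatch_frac: float = 0.01,
                            ) -> QuadripartitePartition:
    """Locate the maximal inverted-repeat pair and partition the circle.

    Seeds: 21-mers of the sequence matched against 21-mers of its reverse
    complement cluster on a single antidiagonal for a true inverted repeat.
    The best antidiagonal's seed span is refined by outward extension at both
    boundary pairs until the running mismatch fraction would exceed
    ``max_mismatch_frac``. The larger of the two gaps between the repeats is
    labelled LSC, the smaller SSC; IRb is the repeat copy that follows the
    LSC in sequence order.

    Raises
    ------
    NoQuadripartiteStructureError
        If no inverted repeat of at least ``min_ir_len`` exists.
    """
    s = seq.sequence if isinstance(seq, PlastomeSequence) else seq.upper()
    n = len(s)
    k = _SEED_K
    if n <= 2 * min_ir_len:
        raise NoQuadripartiteStructureError(
            f"sequence of {n} bp cannot host two IRs of >= {min_ir_len} bp")
    s2 = s + s

    diags = _antidiagonal_hits(s2, n, k)
    if not diags:
        raise NoQuadripartiteStructureError("no inverted-repeat seed matches")

    # best antidiagonal by hit count (ties -> smaller start), then merge the
    # hits of nearby diagonals: indels between the two repeat copies shift
    # seeds onto neighbouring antidiagonals
    best_d = max(diags, key=lambda d: (len(diags[d]), -min(i for i, _ in diags[d])))
    hits = [h for d in diags if abs(d - best_d) <= 64 for h in diags[d]]

    # boundary-defining hits: the outermost i (paired with its own j) fixes
    # the outer junction pairing exactly; the innermost likewise
    i_out, j_out = min(hits)
    i_in, j_in = max(hits)
    b_lo, a_hi = i_out, j_out + k
    b_hi, a_lo = i_in + k, j_in

    b_lo, b_hi, a_lo, a_hi, mism = _extend_ir(s2, n, b_lo, b_hi, a_lo, a_hi,
                                              max_mismatch_frac)
    # the two copies may differ by a few indels; equalize lengths by
    # retracting the longer copy's inner junction
    len_b, len_a = b_hi - b_lo, a_hi - a_lo
    if len_b > len_a:
        b_hi -= len_b - len_a
    elif len_a > len_b:
        a_lo += len_a - len_b
    ir_len = b_hi - b_lo
    if ir_len < min_ir_len:
        raise NoQuadripartiteStructureError(
            f"no quadripartite structure: longest inverted repeat is "
            f"{ir_len} bp (< {min_ir_len} bp)")

    d = edlib.align(s2[b_lo:b_hi], revcomp(s2[a_lo:a_hi]),
                    task="distance")["editDistance"]
    ident = 1.0 - d / ir_len

    inner = a_lo - b_hi              # gap between the repeats, inside
    outer = (b_lo + n) - a_hi        # gap wrapping past the 'i' copy
    if inner <= 0 or outer <= 0:
        raise NoQuadripartiteStructureError("inverted repeats leave no single-copy gap")

    if outer >= inner:
        lsc = (a_hi % n, a_hi % n + outer)
        irb = (b_lo % n, b_lo % n + ir_len)
        ssc = (b_hi % n, b_hi % n + inner)
        ira = (a_lo % n, a_lo % n + ir_len)
    else:
        lsc = (b_hi % n, b_hi % n + inner)
        irb = (a_lo % n, a_lo % n + ir_len)
        ssc = (a_hi % n, a_hi % n + outer)
        ira = (b_lo % n, b_lo % n + ir_len)
    return QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira,
                                  ir_identity=ident)


def _extend_ir(s2: str, n: int, b_lo: int, b_hi: int, a_lo: int, a_hi: int,
               frac: float) -> tuple[int, int, int, int, int]:
    """Extend an IR candidate outward under a running mismatch budget.

    Position b_lo-1 pairs with a_hi (outer side); b_hi pairs with a_lo-1
    (inner side). Matching pairs always extend. A mismatching pair is
    stepped over only while the running mismatch count stays within
    ``frac`` of the repeat length *and* at least 3 of the 4 pairs beyond it
    match (lookahead confirmation) — sparse substitutions inside a true
    repeat pass, the ~75%-mismatch regime of single-copy sequence does not.
    With frac = 0 the extension is exact.
    """
    mism = 0

    def lookahead_ok(pairs) -> bool:
        window = [x == complement(y) for x, y in pairs]
        return sum(window) >= max(0, len(window) - 1) and len(window) == 4

    # inner side: b_hi / a_lo-1 (must keep a gap between the copies)
    while a_lo - 1 > b_hi:
        if s2[b_hi] == complement(s2[a_lo - 1]):
            b_hi += 1
            a_lo -= 1
            continue
        nxt = [(s2[b_hi + 1 + t], s2[a_lo - 2 - t]) for t in range(4)
               if a_lo - 2 - t > b_hi + 1 + t]
        if mism + 1 > frac * ((b_hi - b_lo) + 1) or not lookahead_ok(nxt):
            break
        mism += 1
        b_hi += 1
        a_lo -= 1
    # outer side: b_lo-1 / a_hi (must keep the wrap gap)
    while b_lo - 1 >= 0 and a_hi < b_lo + n:
        if s2[b_lo - 1] == complement(s2[a_hi]):
            b_lo -= 1
            a_hi += 1
            continue
        nxt = [(s2[b_lo - 2 - t], s2[a_hi + 1 + t]) for t in range(4)
               if b_lo - 2 - t >= 0 and a_hi + 1 + t < b_lo + n]
        if mism + 1 > frac * ((b_hi - b_lo) + 1) or not lookahead_ok(nxt):
            break
        mism += 1
        b_lo -= 1
        a_hi += 1
    return b_lo, b_hi, a_lo, a_hi, mism


def canonicalize(seq: PlastomeSequence,
                 partition: QuadripartitePartition | None = None) -> PlastomeSequence:
    """Rotate the circle so position 0 is the LSC start.

    Region order after rotation is LSC - IRb - SSC - IRa with no interval
    wrapping the origin. Idempotent.
    """
    if partition is None:
        partition = seq.partition
    if partition is None:
        raise ConfigError("canonicalize requires a partition")
    n = len(seq.sequence)
    if partition.total_len != n:
        raise ConfigError(
            f"partition total {partition.total_len} != sequence length {n}")
    r = partition.lsc[0] % n
    rotated = seq.sequence[r:] + seq.sequence[:r]

    def shift(iv: tuple[int, int]) -> tuple[int, int]:
        s = (iv[0] - r) % n
        return (s, s + (iv[1] - iv[0]))

    part = QuadripartitePartition(
        lsc=shift(partition.lsc), irb=shift(partition.irb),
        ssc=shift(partition.ssc), ira=shift(partition.ira),
        ir_identity=partition.ir_identity,
    )
    return PlastomeSequence(id=seq.id, sequence=rotated, circular=seq.circular,
                            partition=part)


def _match_fraction(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def normalize_ssc_orientation(seq: PlastomeSequence,
                              partition: QuadripartitePartition | None,
                              reference: PlastomeSequence) -> PlastomeSequence:
    """Flip the SSC iff its reverse complement matches the reference better.

    Resolves the flip-flop degeneracy of assemblies: both SSC orientations
    are equally valid molecules, so comparisons require a conventional one.
    The SSC segment is replaced by its reverse complement exactly when that
    strictly increases the match fraction to the reference SSC; all other
    bases are untouched. Idempotent.
    """
    if partition is None:
        partition = seq.partition
    if partition is None:
        raise ConfigError("sequence lacks a detected partition")
    ref_part = reference.partition
    if ref_part is None:
        try:
            ref_part = detect_inverted_repeats(reference)
        except NoQuadripartiteStructureError as e:
            raise NoQuadripartiteStructureError(
                f"reference lacks a detectable SSC: {e}") from e

    ssc = wrap_slice(seq.sequence, partition.ssc[0] % len(seq.sequence), partition.ssc[1])
    ref_ssc = wrap_slice(reference.sequence,
                         ref_part.ssc[0] % len(reference.sequence), ref_part.ssc[1])
    if _match_fraction(revcomp(ssc), ref_ssc) > _match_fraction(ssc, ref_ssc):
        n = len(seq.sequence)
        start, end = partition.ssc[0] % n, partition.ssc[1] % n or n
        if start < end:
            new = seq.sequence[:start] + revcomp(ssc) + seq.sequence[end:]
        else:  # SSC wraps the origin
            flipped = revcomp(ssc)
            tail = n - start
            new = flipped[tail:] + seq.sequence[end:start] + flipped[:tail]
        return replace(seq, sequence=new, partition=partition)
    return replace(seq, partition=partition)
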