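"""Assembly comparison: difference classification and summary statistics.

Two assemblies are globally aligned; every differing alignment column is
classified as a homonucleotide-run deletion (a gap lying entirely inside a
run of the other sequence), an ambiguity (an IUPAC code on either side), or
a substitution. The summary mirrors the conventional assembly-comparison
table: per-symbol composition, total changes (each missing base counts as
one change) and % dissimilarity (total changes over alignment columns).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from ._seq import AMBIGUITY_CODES, IUPAC_ALPHABET, run_at
from .align import PairwiseAlignment, global_align
from .errors import ConfigError
from .structure import PlastomeSequence

global_banded_align = global_align  # public name for the pairwise aligner


@dataclass(frozen=True)
class DifferenceRecord:
    """One classified difference between two aligned assemblies.

    ``kind`` is ``homopolymer_deletion`` (gap entirely inside a maximal
    homonucleotide run, length >= min_run_len, of the ungapped sequence),
    ``ambiguity`` (IUPAC code on either side of a differing column) or
    ``substitution`` (anything else; a non-run gap keeps its length > 1 and
    is flagged). ``run_id`` identifies the maximal run carrying a gap, in
    the ungapped sequence's own coordinates (side:base:start), so records
    from different alignments sharing a frame sequence are comparable.
    """

    column_start: int
    kind: str  # homopolymer_deletion | substitution | ambiguity
    length: int
    run_base: str | None = None
    run_id: str | None = None
    gap_side: str | None = None  # which sequence ('a'|'b') lacks the bases
    flagged: bool = False
    frame_id: str | None = None


@dataclass(frozen=True)
class ComparisonReport:
    """Machine twin of a two-assembly comparison table."""

    len_a: int
    len_b: int
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    total_changes: int
    pct_dissimilarity: float
    columns: int
    gap_columns: int
    mismatch_columns: int

    def __post_init__(self):
        if sum(self.counts_a.values()) != self.len_a:
            raise ConfigError("counts_a do not sum to len_a")
        if sum(self.counts_b.values()) != self.len_b:
            raise ConfigError("counts_b do not sum to len_b")
        if self.total_changes != self.gap_columns + self.mismatch_columns:
            raise ConfigError("total_changes must equal gap + mismatch columns")

    def to_dict(self) -> dict:
        return {
            "len_a": self.len_a, "len_b": self.len_b,
            "counts_a": dict(self.counts_a), "counts_b": dict(self.counts_b),
            "total_changes": self.total_changes,
            "pct_dissimilarity": self.pct_dissimilarity,
            "columns": self.columns, "gap_columns": self.gap_columns,
            "mismatch_columns": self.mismatch_columns,
        }


@dataclass(frozen=True)
class SharedGapReport:
    """How often two assemblies lose bases from the same homonucleotide runs.

    ``frac_same_region``: fraction of A's run-deletion events whose run also
    carries a deletion in B; ``frac_identical_span``: fraction of A's events
    whose run lost the identical number of bases in both. Both are 0 (and
    ``empty_a`` is set) when A has no run-deletion events.
    """

    frac_same_region: float
    frac_identical_span: float
    n_events_a: int = 0
    n_events_b: int = 0
    empty_a: bool = False

    def __post_init__(self):
        if not 0.0 <= self.frac_identical_span <= self.frac_same_region <= 1.0:
            raise ConfigError("shared-gap fractions must satisfy "
                              "0 <= identical <= same_region <= 1")


def composition_stats(seq: str | PlastomeSequence) -> dict[str, int]:
    """Exact per-symbol tallies; A/C/G/T always present, codes as observed."""
    s = seq.sequence if isinstance(seq, PlastomeSequence) else seq
    for i, ch in enumerate(s):
        if ch not in IUPAC_ALPHABET:
            raise ConfigError(f"invalid character {ch!r} at position {i}")
    counts = Counter(s)
    return {sym: counts.get(sym, 0) for sym in
            ["A", "C", "G", "T"] + sorted(set(counts) - set("ACGT"))}


def _ungapped_pos_map(gapped: str) -> list[int]:
    """For each column, the ungapped position of the symbol (or of the next
    symbol when the column is a gap)."""
    pos, out = 0, []
    for ch in gapped:
        out.append(pos)
        if ch != "-":
            pos += 1
    return out


def classify_differences(aln: PairwiseAlignment, min_run_len: int = 2,
                         frame_id: str | None = None) -> list[DifferenceRecord]:
    """Classify every difference in a pairwise alignment.

    Each maximal gap stretch yields one record; it is a
    ``homopolymer_deletion`` iff the stretch lies entirely inside one
    maximal homonucleotide run (length >= ``min_run_len``) of the ungapped
    other sequence. Differing non-gap columns yield per-column records:
    ``ambiguity`` if either symbol is an IUPAC ambiguity code (or N), else
    ``substitution``.
    """
    ga, gb = aln.gapped_a, aln.gapped_b
    ung_a = "".join(c for c in ga if c != "-")
    ung_b = "".join(c for c in gb if c != "-")
    pos_a = _ungapped_pos_map(ga)
    pos_b = _ungapped_pos_map(gb)

    records: list[DifferenceRecord] = []
    i, ncols = 0, aln.columns
    while i < ncols:
        ca, cb = ga[i], gb[i]
        if ca == "-" or cb == "-":
            gap_in_a = ca == "-"
            gapped, other = (ga, gb) if gap_in_a else (gb, ga)
            j = i
            while j < ncols and gapped[j] == "-":
                j += 1
            length = j - i
            other_seq = ung_b if gap_in_a else ung_a
            other_pos = (pos_b if gap_in_a else pos_a)[i]
            missing = other[i:j]
            run_base = run_id = None
            kind, flagged = "substitution", True
            if len(set(missing)) == 1:
                start, run_len, base = run_at(other_seq, other_pos)
                if run_len >= min_run_len and other_pos + length <= start + run_len:
                    kind, flagged = "homopolymer_deletion", False
                    run_base = base
                    side = "b" if gap_in_a else "a"
                    run_id = f"{side}:{base}:{start}"
            records.append(DifferenceRecord(
                column_start=i, kind=kind, length=length, run_base=run_base,
                run_id=run_id, gap_side="a" if gap_in_a else "b",
                flagged=flagged, frame_id=frame_id))
            i = j
            continue
        if ca != cb:
            kind = ("ambiguity"
                    if ca in AMBIGUITY_CODES or cb in AMBIGUITY_CODES
                    or "N" in (ca, cb) else "substitution")
            records.append(DifferenceRecord(
                column_start=i, kind=kind, length=1, frame_id=frame_id))
        i += 1
    return records


def comparison_report(a: str | PlastomeSequence, b: str | PlastomeSequence,
                      band: int | None = None) -> ComparisonReport:
    """Align two assemblies and summarize their differences.

    ``total_changes`` counts every gap column (each missing base
    individually) plus every differing non-gap column; an ambiguity code
    over a compatible base differs and therefore counts, even though it is
    scored as a match during alignment. ``pct_dissimilarity`` is
    100 * total_changes / columns, rounded half-up to 3 decimals.
    """
    sa = a.sequence if isinstance(a, PlastomeSequence) else a
    sb = b.sequence if isinstance(b, PlastomeSequence) else b
    aln = global_align(sa, sb, band=band)
    gap_cols = sum(1 for x, y in zip(aln.gapped_a, aln.gapped_b)
                   if x == "-" or y == "-")
    mismatch_cols = sum(1 for x, y in zip(aln.gapped_a, aln.gapped_b)
                        if x != "-" and y != "-" and x != y)
    total = gap_cols + mismatch_cols
    pct = float(
        (Decimal(100 * total) / Decimal(aln.columns)).quantize(
            Decimal("0.001"), rounding=ROUND_HALF_UP)
    ) if aln.columns else 0.0
    return ComparisonReport(
        len_a=len(sa), len_b=len(sb),
        counts_a=composition_stats(sa), counts_b=composition_stats(sb),
        total_changes=total, pct_dissimilarity=pct,
        columns=aln.columns, gap_columns=gap_cols,
        mismatch_columns=mismatch_cols)


def shared_gap_stats(diffs_a: list[DifferenceRecord],
                     diffs_b: list[DifferenceRecord]) -> SharedGapReport:
    """Shared homonucleotide-gap statistics across two assemblies.

    Both difference lists must be expressed against the same frame sequence
    (the frame on side 'a' of both alignments), so run identifiers are
    comparable; events are aggregated per run (total missing bases).
    """
    frames = {r.frame_id for r in diffs_a + diffs_b}
    if len(frames) > 1:
        raise ConfigError(f"difference lists built against different frames: {frames}")

    def run_spans(diffs):
        spans: dict[str, int] = {}
        for r in diffs:
            if r.kind == "homopolymer_deletion" and r.run_id is not None:
                if not r.run_id.startswith("a:"):
                    raise ConfigError(
                        "gap events must be expressed against the common frame "
                        "(frame on side 'a' of the alignment)")
                spans[r.run_id] = spans.get(r.run_id, 0) + r.length
        return spans

    spans_a, spans_b = run_spans(diffs_a), run_spans(diffs_b)
    if not spans_a:
        return SharedGapReport(0.0, 0.0, 0, len(spans_b), empty_a=True)
    shared = [rid for rid in spans_a if rid in spans_b]
    identical = [rid for rid in shared if spans_a[rid] == spans_b[rid]]
    return SharedGapReport(
        frac_same_region=len(shared) / len(spans_a),
        frac_identical_span=len(identical) / len(spans_a),
        n_events_a=len(spans_a), n_events_b=len(spans_b))
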