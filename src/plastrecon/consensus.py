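"""Custom assembly reconstruction: contig filtering, anchoring, IUPAC
consensus, and two-tier reconciliation.

This reproduces, as reusable operations, an assembly workflow for long-read
organelle data: contigs are screened by homology to a related-species
reference and a length floor (50 kb by default), each surviving contig is
anchored and aligned into the reference coordinate frame, a per-dataset
consensus is called with IUPAC codes at internally conflicting columns and N
where a base conflicts with a gap, and finally the consensuses of two
read-quality tiers are reconciled column-by-column into a single assembly,
preferring the unambiguous call and — for homonucleotide-run length
disagreements — the shorter run (the conservative solution).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from math import ceil

from . import _seq
from ._seq import iupac_code, iupac_set, revcomp
from .align import gapped_from_cigar, global_align, infix_align
from .errors import AnchorError, ConfigError, CoverageError, NoPlastomeContigsError
from .structure import PlastomeSequence
from .synthetic import Contig, ContigSet

DEFAULT_MIN_CONTIG_LEN = 50_000  # length floor for plastome contigs
DEFAULT_SEED_LEN = 21


@dataclass(frozen=True)
class AlignedContig:
    """A contig aligned into reference coordinates.

    ``aligned_seq`` holds one character per reference position in
    ``ref_interval`` ('-' where the contig lacks the reference base);
    insertions relative to the reference are dropped and counted in
    ``insertions_dropped``. ``ref_interval`` may extend past the reference
    length when the contig wraps the origin of a circular reference.
    """

    contig_id: str
    ref_interval: tuple[int, int]
    aligned_seq: str
    strand: str
    edit_distance: int = 0
    insertions_dropped: int = 0

    def __post_init__(self):
        if len(self.aligned_seq) != self.ref_interval[1] - self.ref_interval[0]:
            raise ConfigError("aligned_seq length must equal the reference interval")


@dataclass
class ConsensusAssembly:
    """A consensus sequence with per-column ambiguity provenance.

    ``ambiguity_positions`` lists (position, code, supporting bases) for
    every non-ACGT, non-N column; ``n_positions`` lists the N columns. Both
    index into ``sequence``. ``ref_coords`` (optional) maps each consensus
    position back to the reference column it was called from.
    """

    sequence: str
    ambiguity_positions: list[tuple[int, str, str]] = field(default_factory=list)
    n_positions: list[int] = field(default_factory=list)
    ref_coords: list[int] | None = None

    def __post_init__(self):
        for pos, code, _bases in self.ambiguity_positions:
            if self.sequence[pos] != code:
                raise ConfigError(f"ambiguity record at {pos} inconsistent with sequence")
        for pos in self.n_positions:
            if self.sequence[pos] != "N":
                raise ConfigError(f"N record at {pos} inconsistent with sequence")

    @classmethod
    def from_sequence(cls, sequence: str,
                      ref_coords: list[int] | None = None) -> "ConsensusAssembly":
        """Build the provenance lists by scanning the sequence."""
        amb, ns = [], []
        for i, ch in enumerate(sequence):
            if ch == "N":
                ns.append(i)
            elif ch in _seq.AMBIGUITY_CODES:
                amb.append((i, ch, "".join(sorted(iupac_set(ch)))))
        return cls(sequence=sequence, ambiguity_positions=amb, n_positions=ns,
                   ref_coords=ref_coords)

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class ResolutionRecord:
    """One reconciled incongruence between the two tier consensuses."""

    position: int  # bp position in the reconciled output
    input_a: str
    input_b: str
    rule_applied: str  # identical | unambiguous_base | homopolymer_minimum
    #                  # | union_ambiguity | n_vs_base
    output: str
    flagged: bool = False  # True when both inputs were ambiguous yet differed


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _reference_kmers(reference: PlastomeSequence, k: int) -> set[str]:
    ref = reference.sequence
    if reference.circular:
        ref = ref + ref[: k - 1]
    return _kmer_set(ref, k) | _kmer_set(revcomp(ref), k)


def filter_contigs(contigs: ContigSet, reference: PlastomeSequence,
                   min_len: int = DEFAULT_MIN_CONTIG_LEN,
                   min_seed_hits: int | None = None,
                   seed_len: int = DEFAULT_SEED_LEN) -> ContigSet:
    """Retain contigs homologous to the reference and >= ``min_len`` bp.

    Homology evidence is the number of contig k-mer positions whose k-mer
    occurs in the reference or its reverse complement; the default threshold
    is 25% of the contig's k-mers. Order is preserved. Raises
    NoPlastomeContigsError if nothing survives.
    """
    if not reference.sequence:
        raise ConfigError("reference must be non-empty")
    ref_kmers = _reference_kmers(reference, seed_len)
    kept = []
    for contig in contigs:
        if len(contig.sequence) < min_len:
            continue
        n_kmers = len(contig.sequence) - seed_len + 1
        if n_kmers <= 0:
            continue
        hits = sum(
            contig.sequence[i : i + seed_len] in ref_kmers for i in range(n_kmers)
        )
        threshold = (min_seed_hits if min_seed_hits is not None
                     else ceil(0.25 * n_kmers))
        if hits >= threshold:
            kept.append(contig)
    if not kept:
        raise NoPlastomeContigsError(
            f"no contigs pass the plastome filter "
            f"(min_len={min_len}, {len(contigs)} candidates)")
    return ContigSet(kept, error_log=contigs.error_log)


def _seed_diagonals(contig: str, ref2: str, k: int, stride: int,
                    index: dict[str, list[int]]) -> list[int]:
    diags = []
    for i in range(0, len(contig) - k + 1, stride):
        for j in index.get(contig[i : i + k], ()):
            diags.append(j - i)
    return diags


def anchor_align_to_reference(contig: Contig | str, reference: PlastomeSequence,
                              seed_len: int = DEFAULT_SEED_LEN,
                              band: int = 256) -> AlignedContig:
    """Anchor a contig on the reference by seed k-mers and align it.

    The strand with the majority of k-mer hits is chosen; the dominant seed
    diagonal locates a reference window (padded by ``band``), and the contig
    is aligned to the window with free end-gaps, yielding the optimal infix
    alignment under unit edit costs. The gapped sequence is re-expressed in
    reference columns; insertion columns (bases the reference lacks) are
    dropped and counted.
    """
    cid = contig.id if isinstance(contig, Contig) else "contig"
    cseq = contig.sequence if isinstance(contig, Contig) else contig
    ref = reference.sequence
    n = len(ref)
    ref2 = ref + ref if reference.circular else ref
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(ref2) - seed_len + 1):
        index[ref2[j : j + seed_len]].append(j)

    stride = max(1, len(cseq) // 512)
    fwd = _seed_diagonals(cseq, ref2, seed_len, stride, index)
    rc_seq = revcomp(cseq)
    rc = _seed_diagonals(rc_seq, ref2, seed_len, stride, index)
    if not fwd and not rc:
        raise AnchorError(f"contig {cid!r}: no seed anchors on the reference")
    strand = "+" if len(fwd) >= len(rc) else "-"
    query = cseq if strand == "+" else rc_seq
    diags = fwd if strand == "+" else rc

    # dominant diagonal cluster (bucketed), then its median
    buckets = Counter(d // 250 for d in diags)
    top = buckets.most_common(1)[0][0]
    cluster = sorted(d for d in diags if abs(d // 250 - top) <= 1)
    offset = cluster[len(cluster) // 2] % n

    w_lo = max(0, offset - band)
    w_hi = min(len(ref2), offset + len(query) + band)
    dist, t_start, t_end, cigar = infix_align(query, ref2[w_lo:w_hi])
    gq, gt = gapped_from_cigar(query, ref2, cigar, t_start=w_lo + t_start)

    aligned, dropped = [], 0
    for qc, tc in zip(gq, gt):
        if tc == "-":
            dropped += 1  # insertion relative to the reference
        else:
            aligned.append(qc)
    start = w_lo + t_start
    end = start + len(aligned)
    if start >= n:
        start, end = start - n, end - n
    return AlignedContig(contig_id=cid, ref_interval=(start, end),
                         aligned_seq="".join(aligned), strand=strand,
                         edit_distance=dist, insertions_dropped=dropped)


def build_iupac_consensus(aligned: list[AlignedContig],
                          reference_length: int) -> ConsensusAssembly:
    """Column-wise IUPAC consensus over contigs in the reference frame.

    Per reference column: agreement -> the base; two or more distinct bases
    (no gap) -> the IUPAC code of the observed set; any base-vs-gap conflict
    -> N; gap in every covering contig -> the column is dropped. Columns
    covered by no contig raise CoverageError (absence of data is an error,
    not an N — N is reserved for observed conflict).
    """
    if not aligned:
        raise ConfigError("consensus requires at least one aligned contig")
    columns: list[list[str]] = [[] for _ in range(reference_length)]
    for ac in aligned:
        start, _ = ac.ref_interval
        for idx, ch in enumerate(ac.aligned_seq):
            columns[(start + idx) % reference_length].append(ch)

    uncovered = [i for i, col in enumerate(columns) if not col]
    if uncovered:
        gaps, s = [], uncovered[0]
        for prev, cur in zip(uncovered, uncovered[1:]):
            if cur != prev + 1:
                gaps.append((s, prev + 1))
                s = cur
        gaps.append((s, uncovered[-1] + 1))
        raise CoverageError(gaps)

    out, amb, ns, coords = [], [], [], []
    for ref_pos, col in enumerate(columns):
        bases = [c for c in col if c != "-"]
        if not bases:
            continue  # deletion agreed by every contig: column dropped
        if len(bases) < len(col):
            sym = "N"  # base vs gap conflict
        else:
            union = frozenset().union(*(iupac_set(c) for c in bases))
            sym = iupac_code(union) if union != frozenset("ACGT") else "N"
        pos = len(out)
        out.append(sym)
        coords.append(ref_pos)
        if sym == "N":
            ns.append(pos)
        elif sym in _seq.AMBIGUITY_CODES:
            amb.append((pos, sym, "".join(sorted(set(bases)))))
    return ConsensusAssembly(sequence="".join(out), ambiguity_positions=amb,
                             n_positions=ns, ref_coords=coords)


def reconcile_consensuses(a: ConsensusAssembly, b: ConsensusAssembly,
                          ) -> tuple[ConsensusAssembly, list[ResolutionRecord]]:
    """Merge two tier consensuses into one assembly, logging every decision.

    The two sequences are globally aligned (ambiguity codes match compatible
    symbols) and resolved per column or per gap run, in fixed rule order:

    1. identical symbols -> kept (not logged);
    2. ambiguity code vs a compatible concrete base -> the concrete base
       (``unambiguous_base``; ``n_vs_base`` when the ambiguous side is N);
    3. gap stretch inside a homonucleotide run (length >= 2) of the
       base-carrying side -> the shorter run, i.e. the extra bases are
       dropped (``homopolymer_minimum``); a gap stretch *outside* any run is
       not a run-length disagreement — dropping it would fuse its flanking
       runs into a longer one — so the called bases are kept
       (``unambiguous_base``: a concrete call against no call);
    4. two incompatible or differing concrete symbols -> the IUPAC code of
       the union of their base sets (``union_ambiguity``; flagged when both
       sides were already ambiguous);
    5. N vs N -> N (case of rule 1).

    The operation is commutative and idempotent: inputs are put in a
    canonical order internally, so both argument orders perform the
    identical computation and return identical results.
    """
    if b.sequence < a.sequence:
        a, b = b, a
    aln = global_align(a.sequence, b.sequence)
    ga, gb = aln.gapped_a, aln.gapped_b
    ung_a = a.sequence
    ung_b = b.sequence
    pos_a = pos_b = 0  # ungapped cursors

    out: list[str] = []
    out_len = 0
    records: list[ResolutionRecord] = []
    i, ncols = 0, len(ga)
    while i < ncols:
        ca, cb = ga[i], gb[i]
        if "-" in (ca, cb):
            j = i
            gap_in_a = ca == "-"
            while j < ncols and (ga[j] if gap_in_a else gb[j]) == "-" \
                    and (gb[j] if gap_in_a else ga[j]) != "-":
                j += 1
            bases = gb[i:j] if gap_in_a else ga[i:j]
            carrier, carrier_pos = (ung_b, pos_b) if gap_in_a else (ung_a, pos_a)
            in_run = False
            if len(set(bases)) == 1:
                _, run_len, _ = _seq.run_at(carrier, carrier_pos)
                in_run = run_len >= 2
            if in_run:
                rule, kept = "homopolymer_minimum", ""
            else:
                rule, kept = "unambiguous_base", bases
            records.append(ResolutionRecord(
                position=out_len,
                input_a="-" * (j - i) if gap_in_a else bases,
                input_b=bases if gap_in_a else "-" * (j - i),
                rule_applied=rule,
                output=kept))
            out.append(kept)
            out_len += len(kept)
            if gap_in_a:
                pos_b += j - i
            else:
                pos_a += j - i
            i = j
            continue
        if ca == cb:
            out.append(ca)
            out_len += 1
            pos_a += 1
            pos_b += 1
            i += 1
            continue
        sa, sb = iupac_set(ca), iupac_set(cb)
        if len(sa) == 1 and len(sb) > 1 and ca in sb:
            rule = "n_vs_base" if cb == "N" else "unambiguous_base"
            res = ca
        elif len(sb) == 1 and len(sa) > 1 and cb in sa:
            rule = "n_vs_base" if ca == "N" else "unambiguous_base"
            res = cb
        else:
            rule = "union_ambiguity"
            res = iupac_code(sa | sb) if sa | sb != frozenset("ACGT") else "N"
        records.append(ResolutionRecord(
            position=out_len, input_a=ca, input_b=cb, rule_applied=rule,
            output=res, flagged=(len(sa) > 1 and len(sb) > 1)))
        out.append(res)
        out_len += 1
        pos_a += 1
        pos_b += 1
        i += 1

    merged = ConsensusAssembly.from_sequence("".join(out))
    return merged, records


def assemble_tier(contigs: ContigSet, reference: PlastomeSequence,
                  min_len: int = DEFAULT_MIN_CONTIG_LEN,
                  min_seed_hits: int | None = None,
                  seed_len: int = DEFAULT_SEED_LEN,
                  band: int = 256) -> ConsensusAssembly:
    """Filter -> anchor-align -> IUPAC consensus for one quality tier."""
    kept = filter_contigs(contigs, reference, min_len=min_len,
                          min_seed_hits=min_seed_hits, seed_len=seed_len)
    aligned = [anchor_align_to_reference(c, reference, seed_len=seed_len, band=band)
               for c in kept]
    return build_iupac_consensus(aligned, len(reference.sequence))
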