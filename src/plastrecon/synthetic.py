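"""Synthetic plastomes with ONT-style errors and fragmented contig sets.

The generator emulates the data a long-read plastome assembly project sees:
a circular quadripartite genome (LSC - IRb - SSC - IRa, with IRa the exact
reverse complement of IRb), consensus-level Nanopore error structure
(deletions concentrated in homonucleotide runs, with multi-base gaps up to a
cap; substitutions with A<->T miscalls down-weighted), and contig sets from
two read-quality tiers standing in for q8/q9 quality-filtered assemblies.

All coordinates are 0-based, half-open on the linearized circle (position 0 =
LSC start); intervals may extend past the sequence length to denote wrapping
past the origin. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` streams split per operation, so adding one
operation never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _seq
from ._seq import BASES, complement, random_sequence, revcomp, wrap_slice
from .errors import ConfigError
from .structure import QuadripartitePartition

# Region lengths of a representative Heliantheae (Asteraceae) plastome, the default
# simulated genome geometry (total 152,050 bp).
DEFAULT_LSC_LEN = 83_721
DEFAULT_SSC_LEN = 18_241
DEFAULT_IR_LEN = 25_044


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry and composition of a simulated circular plastome.

    Parameters
    ----------
    lsc_len, ssc_len, ir_len
        Region lengths in bp; the genome totals ``lsc + ssc + 2*ir``.
    gc_fraction
        Expected GC content. Default 0.377 is the AT-rich composition
        typical of Asteraceae plastomes.
    homopolymer_enrichment
        Expected number of planted homonucleotide runs (length 4-10) per
        10 kb, on top of runs arising by chance.
    rng_seed
        Master seed; the same seed always yields the identical genome.
    """

    lsc_len: int = DEFAULT_LSC_LEN
    ssc_len: int = DEFAULT_SSC_LEN
    ir_len: int = DEFAULT_IR_LEN
    gc_fraction: float = 0.377
    homopolymer_enrichment: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ConfigError("region lengths must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must lie in [0, 1]")
        if self.homopolymer_enrichment < 0:
            raise ConfigError("homopolymer_enrichment must be non-negative")

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class ErrorModel:
    """Consensus-level ONT error model.

    Substitutions are per-base Bernoulli(`p_sub`) with the alternative drawn
    uniformly from the three other bases; a drawn A<->T swap is then rejected
    with probability ``1 - at_miscall_weight`` (A<->T miscalls are the least
    likely ONT substitution class). Deletions act per maximal homonucleotide
    run of length L with one Bernoulli trial at

        p_del(L) = min(1, p_del_base + p_del_slope * (L - 1)),

    non-decreasing in L; the deleted span is truncated-geometric(1/2) capped
    at ``max_del_len`` (multi-base gaps up to 7 bp are seen in real ONT
    assemblies) and at the run length. A homonucleotide run is two or more
    identical bases: single-base "runs" take no deletion trial, matching the
    observation that essentially all residual ONT consensus gaps sit inside
    such runs.
    """

    p_sub: float = 2e-5
    at_miscall_weight: float = 0.2
    p_del_base: float = 0.0003
    p_del_slope: float = 0.007
    max_del_len: int = 7

    def __post_init__(self):
        for name in ("p_sub", "at_miscall_weight", "p_del_base", "p_del_slope"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.max_del_len < 1:
            raise ConfigError("max_del_len must be >= 1")

    def p_del(self, run_len: int) -> float:
        return min(1.0, self.p_del_base + self.p_del_slope * (run_len - 1))


#: Default error models for the two read-quality tiers. The q8 tier admits
#: lower-quality reads and therefore carries the higher residual error; the
#: rates are set so one 152 kb assembly accrues a few hundred homonucleotide
#: gap bases and a handful of substitutions, the magnitudes seen in real
#: ONT plastome consensus sequences.
Q8_ERROR_MODEL = ErrorModel(p_sub=3e-5, p_del_base=0.0002, p_del_slope=0.004)
Q9_ERROR_MODEL = ErrorModel(p_sub=2e-5, p_del_base=0.00012, p_del_slope=0.003)


@dataclass(frozen=True)
class ErrorEvent:
    position: int  # 0-based position in the input (truth-frame) sequence
    kind: str  # "substitution" | "deletion"
    detail: str | int  # new base, or deleted span length


@dataclass
class ErrorLog:
    events: list[ErrorEvent] = field(default_factory=list)

    def replay(self, seq: str) -> str:
        """Apply the recorded events to ``seq``; reproduces the corrupted copy."""
        out = []
        i = 0
        for ev in self.events:
            out.append(seq[i : ev.position])
            if ev.kind == "substitution":
                out.append(str(ev.detail))
                i = ev.position + 1
            else:
                i = ev.position + int(ev.detail)
        out.append(seq[i:])
        return "".join(out)


@dataclass
class TruthGenome:
    sequence: str
    partition: QuadripartitePartition
    planted_runs: list[tuple[int, str, int]]  # (start, base, length)
    config: SimulationConfig | None = None

    def region(self, name: str) -> str:
        start, end = getattr(self.partition, name)
        return wrap_slice(self.sequence, start, end)


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    truth_interval: tuple[int, int]  # end may exceed genome length (wrap)
    strand: str  # "+" | "-"


@dataclass
class ContigSet:
    contigs: list[Contig]
    #: injected-error events in truth coordinates (may repeat across
    #: overlapping contigs); None for noiseless sets
    error_log: ErrorLog | None = None

    def __post_init__(self):
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ConfigError("contig ids must be unique")
        if any(not c.sequence for c in self.contigs):
            raise ConfigError("contig sequences must be non-empty")

    def __len__(self):
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)


def _plant_runs(seq_arr: np.ndarray, region: tuple[int, int], rate_per_10kb: float,
                rng: np.random.Generator) -> list[tuple[int, str, int]]:
    start, end = region
    span = end - start
    n_runs = rng.poisson(rate_per_10kb * span / 10_000)
    planted = []
    for _ in range(n_runs):
        length = int(rng.integers(4, 11))
        pos = start + int(rng.integers(0, max(1, span - length)))
        base = BASES[int(rng.integers(0, 4))]
        seq_arr[pos : pos + length] = base
        planted.append((pos, base, length))
    return planted


def simulate_plastome(config: SimulationConfig) -> TruthGenome:
    """Generate a circular quadripartite plastome with known coordinates.

    The IRa segment is the exact reverse complement of IRb. Homonucleotide
    runs are planted uniformly in LSC, SSC and IRb (mirrored into IRa) and
    recorded alongside the partition. The four region junctions are adjusted
    so the planted IR pair is the *maximal* inverted repeat: the single-copy
    bases flanking the IRs never extend the repeat by chance.
    """
    lsc, ssc, ir = config.lsc_len, config.ssc_len, config.ir_len
    ss = np.random.SeedSequence(config.rng_seed)
    rng_seq, rng_runs = (np.random.default_rng(s) for s in ss.spawn(2))

    # unique portion: LSC + IRb + SSC; IRa is derived
    unique = random_sequence(rng_seq, lsc + ir + ssc, config.gc_fraction)
    arr = np.array(list(unique))
    planted: list[tuple[int, str, int]] = []
    for region in ((0, lsc), (lsc, lsc + ir), (lsc + ir, lsc + ir + ssc)):
        planted.extend(_plant_runs(arr, region, config.homopolymer_enrichment, rng_runs))

    irb = "".join(arr[lsc : lsc + ir])
    # mirror IRb-planted runs into IRa coordinates
    ira_start = lsc + ir + ssc
    for pos, base, length in [p for p in planted if lsc <= p[0] < lsc + ir]:
        t = pos - lsc
        planted.append((ira_start + ir - (t + length), complement(base), length))

    seq = "".join(arr[:lsc]) + irb + "".join(arr[lsc + ir :]) + revcomp(irb)
    seq = _break_junction_complementarity(seq, lsc, ir, ssc)

    total = config.total_len
    partition = QuadripartitePartition(
        lsc=(0, lsc),
        irb=(lsc, lsc + ir),
        ssc=(lsc + ir, lsc + ir + ssc),
        ira=(lsc + ir + ssc, total),
        ir_identity=1.0,
    )
    planted.sort()
    return TruthGenome(sequence=seq, partition=partition, planted_runs=planted,
                       config=config)


def _break_junction_complementarity(seq: str, lsc: int, ir: int, ssc: int,
                                    guard: int = 3) -> str:
    """Ensure the IR pair cannot be extended across its junctions.

    The planted repeat is maximal only if the flanking single-copy bases do
    not continue the inverted complementarity: extension of the inner
    boundary would pair the first SSC bases with the last SSC bases, and
    extension of the outer boundary the last LSC bases with the first LSC
    bases (across the origin). A ``guard`` of consecutive non-complementary
    pairs is enforced at each junction by deterministically re-drawing the
    first-SSC / last-LSC side bases where needed.
    """
    arr = list(seq)
    ssc_start = lsc + ir
    ssc_end = lsc + ir + ssc
    for t in range(min(guard, ssc // 2)):
        # inner junction pair t: seq[ssc_start + t] vs seq[ssc_end - 1 - t]
        if arr[ssc_start + t] == complement(arr[ssc_end - 1 - t]):
            for b in BASES:
                if b != complement(arr[ssc_end - 1 - t]):
                    arr[ssc_start + t] = b
                    break
    for t in range(min(guard, lsc // 2)):
        # outer junction pair t: seq[lsc - 1 - t] vs seq[t] (wraps the origin)
        if arr[lsc - 1 - t] == complement(arr[t]):
            for b in BASES:
                if b != complement(arr[t]):
                    arr[lsc - 1 - t] = b
                    break
    return "".join(arr)


def apply_ont_errors(seq: str, model: ErrorModel, seed: int) -> tuple[str, ErrorLog]:
    """Corrupt a sequence under the ONT error model; return (copy, log).

    Every deletion event lies inside a maximal homonucleotide run of the
    input and spans at most ``model.max_del_len`` bases; the log replayed
    against the input reproduces the output exactly.
    """
    if not seq:
        raise ConfigError("cannot corrupt an empty sequence")
    rng = np.random.default_rng(seed)
    n = len(seq)

    # substitutions: vectorized Bernoulli, then per-hit alternative draw
    sub_hits = np.flatnonzero(rng.random(n) < model.p_sub)
    subs: dict[int, str] = {}
    for pos in sub_hits:
        orig = seq[pos]
        alts = [b for b in BASES if b != orig]
        alt = alts[int(rng.integers(0, 3))]
        if {orig, alt} == {"A", "T"} and rng.random() >= model.at_miscall_weight:
            continue  # A<->T miscall rejected
        subs[int(pos)] = alt

    # deletions: one trial per maximal homonucleotide run (length >= 2)
    runs = [r for r in _seq.maximal_runs(seq) if r[1] >= 2]
    lengths = np.array([r[1] for r in runs], dtype=int)
    p = np.minimum(1.0, model.p_del_base + model.p_del_slope * (lengths - 1))
    del_hits = rng.random(len(runs)) < p
    spans = np.minimum(rng.geometric(0.5, size=len(runs)), model.max_del_len)

    deletions: dict[int, int] = {}
    for idx in np.flatnonzero(del_hits):
        start, length, _ = runs[idx]
        span = int(min(spans[idx], length))
        deletions[start] = span

    events: list[ErrorEvent] = []
    for pos in sorted(set(subs) | set(deletions)):
        if pos in deletions:
            span = deletions[pos]
            events.append(ErrorEvent(pos, "deletion", span))
            for p_ in range(pos, pos + span):
                subs.pop(p_, None)  # deletion wins over substitution
        elif pos in subs:
            events.append(ErrorEvent(pos, "substitution", subs[pos]))
    events.sort(key=lambda e: e.position)

    log = ErrorLog(events=events)
    return log.replay(seq), log


def fragment_into_contigs(seq: str, n_contigs: int, min_overlap: int = 1000,
                          min_len: int = 1, revcomp_fraction: float = 0.0,
                          seed: int = 0) -> ContigSet:
    """Split a circular sequence into overlapping contigs covering the circle.

    Breakpoints are jittered around an even spacing; each contig extends past
    the next breakpoint by at least ``min_overlap``. A fraction of contigs is
    stored reverse-complemented. The single-contig case returns the
    linearized input itself.
    """
    n = len(seq)
    rng = np.random.default_rng(seed)
    if n_contigs < 1:
        raise ConfigError("n_contigs must be >= 1")
    if n_contigs == 1:
        strand = "-" if rng.random() < revcomp_fraction else "+"
        s = revcomp(seq) if strand == "-" else seq
        return ContigSet([Contig("contig_00", s, (0, n), strand)])

    seg = n // n_contigs
    if seg + min_overlap < min_len:
        raise ConfigError(
            f"min_len={min_len} infeasible: {n_contigs} contigs of a {n} bp "
            f"circle average {seg} bp + {min_overlap} bp overlap")
    if min_overlap >= seg:
        raise ConfigError(
            f"min_overlap={min_overlap} must be smaller than the average "
            f"segment length {seg}")

    jitter = seg // 8
    bounds = []
    for i in range(n_contigs):
        b = i * n // n_contigs
        if jitter and i > 0:
            b += int(rng.integers(-jitter, jitter + 1))
        bounds.append(b % n)
    bounds.sort()

    contigs = []
    for i in range(n_contigs):
        start = bounds[i]
        nxt = bounds[(i + 1) % n_contigs] + (n if i == n_contigs - 1 else 0)
        ov = min_overlap + int(rng.integers(0, max(1, min_overlap)))
        end = nxt + ov
        end = min(end, start + n)  # never exceed one full turn
        if end - start < min_len:
            end = min(start + min_len, start + n)
        s = wrap_slice(seq, start, end)
        strand = "-" if rng.random() < revcomp_fraction else "+"
        if strand == "-":
            s = revcomp(s)
        contigs.append(Contig(f"contig_{i:02d}", s, (start, end), strand))
    return ContigSet(contigs)


def _map_log_to_truth(log: ErrorLog, contig: Contig, genome_len: int) -> list[ErrorEvent]:
    """Re-express contig-local error events in truth coordinates."""
    start, end = contig.truth_interval
    out = []
    for ev in log.events:
        if contig.strand == "+":
            pos = (start + ev.position) % genome_len
            detail = ev.detail
        else:
            if ev.kind == "deletion":
                span = int(ev.detail)
                pos = (end - ev.position - span) % genome_len
                detail = span
            else:
                pos = (end - 1 - ev.position) % genome_len
                detail = complement(str(ev.detail))
        out.append(ErrorEvent(pos, ev.kind, detail))
    out.sort(key=lambda e: e.position)
    return out


def make_quality_tier_pair(truth: TruthGenome, model_hi: ErrorModel = Q8_ERROR_MODEL,
                           model_lo: ErrorModel = Q9_ERROR_MODEL, seed: int = 0,
                           n_contigs: int = 3, min_overlap: int = 2000,
                           revcomp_fraction: float = 0.5) -> tuple[ContigSet, ContigSet]:
    """Two independently fragmented, independently corrupted contig sets.

    ``model_hi`` (the higher error rates) stands in for the q8 quality tier,
    ``model_lo`` for q9. Fragmentation happens first and each contig is then
    corrupted with its own RNG stream, so contigs within one tier can
    disagree in their overlaps — the source of intra-tier consensus
    ambiguities. Each returned ContigSet carries its injected-error log in
    truth coordinates.
    """
    for fld in ("p_sub", "p_del_base", "p_del_slope"):
        if getattr(model_lo, fld) > getattr(model_hi, fld):
            raise ConfigError(f"model_lo.{fld} exceeds model_hi.{fld}")
    n = len(truth.sequence)
    ss = np.random.SeedSequence(seed)
    frag_hi, err_hi, frag_lo, err_lo = ss.spawn(4)

    def _tier(frag_ss, err_ss, model):
        frag_seed = int(frag_ss.generate_state(1)[0] % (2**31))
        contigs = fragment_into_contigs(truth.sequence, n_contigs, min_overlap,
                                        revcomp_fraction=revcomp_fraction,
                                        seed=frag_seed)
        corrupted, all_events = [], []
        for contig, child in zip(contigs, err_ss.spawn(len(contigs))):
            cseed = int(child.generate_state(1)[0] % (2**31))
            seq, log = apply_ont_errors(contig.sequence, model, cseed)
            corrupted.append(replace(contig, sequence=seq))
            all_events.extend(_map_log_to_truth(log, contig, n))
        all_events.sort(key=lambda e: e.position)
        return ContigSet(corrupted, error_log=ErrorLog(all_events))

    return _tier(frag_hi, err_hi, model_hi), _tier(frag_lo, err_lo, model_lo)
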