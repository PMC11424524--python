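# Methods

This note records the models, conventions and design choices behind
`plastrecon`, in the order the pipeline runs them. Coordinates are 0-based
and half-open throughout; on circular sequences an interval's end may exceed
the sequence length to denote wrapping past the origin (position 0 is the
LSC start on the canonical rotation).

## Synthetic genomes

`simulate_plastome` draws a circular genome LSC + IRb + SSC + IRa with IRa
the exact reverse complement of IRb. Defaults are the geometry of a real
Asteraceae plastome — LSC 83,721 bp, SSC 18,241 bp, IR 2 × 25,044 bp,
total 152,050 bp — at GC 0.377, the AT-rich composition typical of these
genomes. Homonucleotide runs of length 4–10 are planted uniformly at an
expected 10 per 10 kb (on top of runs arising by chance in AT-rich random
sequence) in LSC, SSC and IRb, and mirrored into IRa; the planted registry
is returned with the genome. Two properties are enforced so that structural
detection has a well-defined answer:

- the planted IR pair is *maximal*: at each junction the three flanking
  single-copy base pairs are re-drawn if they would extend the inverted
  complementarity by chance (a "junction guard");
- the partition tiles the sequence exactly and is carried on the genome.

All randomness flows from `numpy.random.SeedSequence` streams spawned per
operation, so the same master seed always yields the identical artifact and
adding an operation never perturbs the draws of another.

## ONT error model

The model represents *consensus-level* residual error of a long-read
assembly, not raw-read error. Substitutions are per-base Bernoulli(p_sub);
the alternative base is drawn uniformly from the three others and an A↔T
swap is then rejected with probability 1 − `at_miscall_weight` (default
0.2), realizing the observation that A↔T miscalls are the least likely
substitution class. Deletions take one Bernoulli trial per maximal
homonucleotide run (length L ≥ 2) at

    p_del(L) = min(1, p_del_base + p_del_slope · (L − 1)),

non-decreasing in L; the deleted span is truncated-geometric(1/2), capped at
`max_del_len` = 7 (multi-base gaps up to 7 bp occur in real ONT assemblies)
and at the run length. Single-base positions take no deletion trial:
essentially all residual ONT consensus gaps sit inside homonucleotide
regions, here defined (as is conventional) as runs of two or more identical
bases. Every event is logged with its position; replaying the log against
the input reproduces the corrupted copy exactly.

Default tier models stand in for the q8 (higher residual error) and q9
tiers: q8 p_sub 3·10⁻⁵, p_del_base 2·10⁻⁴, slope 4·10⁻³; q9 p_sub 2·10⁻⁵,
p_del_base 1.2·10⁻⁴, slope 3·10⁻³. These were chosen once so that a 152 kb
assembly accrues a few hundred homonucleotide gap bases and a handful of
substitution-level conflicts — the magnitudes reported for real ONT plastome
assemblies; the true underlying q8/q9 rates are unknown, so tests assert
only their relative order, never absolute hardware fidelity.

`make_quality_tier_pair` fragments the truth first and corrupts each contig
independently (disjoint RNG streams): contigs within one tier can then
disagree in their overlaps, which is the actual source of intra-tier IUPAC
ambiguities in a consensus. Per-tier logs are re-expressed in truth
coordinates so downstream checks can ask whether an output conflict
coincides with an injected error.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: raw reads, quality strings and basecalling;
IR-internal divergence and structural rearrangements; insertion errors;
and, importantly, *systematic* basecaller behaviour. Real ONT datasets
delete from the same long runs in independent sequencing runs (published
shared-gap fractions are ~60% same-region / ~50% identical-span); this
generator draws errors independently per tier, so cross-tier shared-gap
fractions on simulated data are near zero. The shared-gap statistic itself
is exercised against hand-enumerated fixtures.

## Structural detection and normalization

`detect_inverted_repeats` matches 21-mers of the doubled sequence against
its reverse complement; a true inverted repeat clusters on one antidiagonal
(i + j constant). The best antidiagonal is taken by seed count (ties to the
smaller start), hits of neighbouring diagonals (±64) are merged — indels
between the two copies shift seeds onto adjacent antidiagonals — and the
outermost/innermost hits fix the two junction pairings exactly. Boundaries
are then extended outward: a matching pair always extends; a mismatching
pair is stepped over only while the running mismatch count stays within
`max_mismatch_frac` (default 0.01, "nearly identical") of the repeat length
*and* at least 3 of the next 4 pairs match. The lookahead stops extension at
a true boundary (where single-copy sequence mismatches ~75% of the time)
instead of letting the budget pay its way into it; with
`max_mismatch_frac = 0` extension is exact. If the two copies end up with
unequal lengths (possible when they differ by indels) the longer copy's
inner junction is retracted to equalize; `ir_identity` is 1 − edit
distance / IR length. The larger single-copy gap is labelled LSC and IRb is
the copy that follows the LSC. Detection assumes the repeat copies diverge
by substitutions and sparse indels only (the norm for real plastomes) and
does not model IR expansion/contraction.

`canonicalize` rotates the circle so the LSC starts at position 0
(idempotent). `normalize_ssc_orientation` replaces the SSC by its reverse
complement iff that strictly increases the match fraction (1 − edit
distance / length) to the reference SSC — the two orientations are equally
valid molecules, so a convention is required before comparison; match-
fraction maximization is this package's choice of convention. Strictness
makes the operation idempotent.

## Reconstruction

Contig filtering keeps contigs of ≥ 50,000 bp (the published cut-off,
implemented as ≥) whose shared-21-mer count against the reference (or its
reverse complement) reaches 25% of the contig's k-mers — a deliberately
coarse homology screen standing in for a BLAST search against a related
plastome. Anchoring picks the strand with the k-mer hit majority and the
dominant seed diagonal, then aligns the contig to a reference window padded
by `band` (default 256) columns with free end-gaps (edlib HW mode),
yielding the optimal infix alignment under unit edit costs. The gapped
contig is re-expressed with one character per reference column; insertion
columns relative to the reference are dropped and counted (the simulator
produces none, so on synthetic data this is lossless).

The per-tier consensus is called per reference column: agreement gives the
base; two or more distinct bases with no gap give the IUPAC code of the
observed set; any base-vs-gap conflict gives N; a column gapped in every
covering contig is dropped. N is reserved for *observed conflict* — a
reference position covered by no contig is a hard error, not an N.
Coverage ≥ 1 suffices.

`reconcile_consensuses` globally aligns the two tier consensuses (IUPAC
codes score as matches against compatible symbols) and resolves, in fixed
order: identical columns are kept; an ambiguity code against a compatible
concrete base yields the concrete base (the call "without ambiguity"); a
uniform gap stretch lying inside a homonucleotide run (≥ 2) of the
base-carrying side is resolved to the *shorter* run (the solution with the
fewest repeated nucleotides); any other gap stretch keeps the called bases
— dropping a singleton base that separates two runs would fuse them into a
run longer than either input carries, which both the conservative principle
and the run-monotonicity invariant forbid; two differing concrete symbols
yield the IUPAC code of the union of their base sets, so a genuine
disagreement survives into the final assembly as a code. Columns where both
sides are ambiguous yet different are unioned and flagged rather than
guessed. The two inputs are put in a canonical (lexicographic) order before
alignment, making the operation exactly commutative; every non-identical
column or run produces one logged resolution record.

## Comparison statistics

Assemblies are aligned globally under unit edit costs (edlib; adaptively
banded but provably optimal, and checked in tests against an independent
full-DP implementation). An IUPAC code over a compatible base scores as a
match during alignment but still *differs*, so it counts as a change —
required for ambiguities to contribute to the change total without
distorting the alignment path. Conventions:

- **total changes** = gap columns (each missing base individually) +
  differing non-gap columns; this is the only convention that reproduces
  the published decompositions 300 = 255 gap bases + 45 ambiguities and
  221 = 221 + 0;
- **% dissimilarity** = 100 · total_changes / alignment columns, rounded
  half-up to 3 decimals (255 gap + 45 code columns on a 152,050-column
  frame → 0.197%; 221/152,050 → 0.145%);
- a maximal gap stretch is one **homopolymer_deletion** record iff it lies
  entirely inside a maximal run (≥ `min_run_len`, default 2) of the
  ungapped sequence; a differing column with a code on either side is an
  **ambiguity**; everything else is a **substitution** (a non-run gap keeps
  its length and is flagged);
- **shared-gap statistics** aggregate run-deletion events per run of the
  common frame sequence: the fraction of A's affected runs also affected in
  B, and the fraction whose missing-base counts are identical. Both lists
  must be classified against the same frame (enforced via run identifiers);
  an empty A list returns (0, 0) flagged.

## Problem sizes and numerical choices

The default test suite runs the full 152,050 bp genome through the
zero-error round trip and the noisy end-to-end checks (a few seconds each),
and verifies the aligner against the independent DP oracle on 200+ random
pairs up to 2 kb; unit tests use 4–6 kb genomes. Ties everywhere break
deterministically (smaller coordinate first); percentages use decimal
half-up rounding, never float printing; FASTA is wrapped at 70 columns with
circularity carried as a `circular=true` description token, since FASTA has
no standard flag.

## Known limitations

Detection of IRs under heavy indel divergence between the copies is
approximate (boundaries equalized by retraction); the error model has no
insertions and no cross-tier correlation; consensus building cannot
represent insertions relative to the reference frame; and the shared-gap
fractions of real paired ONT assemblies are not reproduced emergently by
the independent-error generator (see above).
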