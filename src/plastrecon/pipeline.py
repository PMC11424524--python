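"""End-to-end pipeline: simulate -> assemble tiers -> reconcile -> normalize
-> compare.

One function drives the whole workflow on synthetic data so that the
complete chain is exercised (and is what the ``pipeline`` CLI subcommand
runs). All randomness flows from the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compare import (
    DifferenceRecord,
    SharedGapReport,
    ComparisonReport,
    classify_differences,
    comparison_report,
    global_banded_align,
    shared_gap_stats,
)
from .consensus import ConsensusAssembly, ResolutionRecord, assemble_tier, \
    reconcile_consensuses
from .errors import NoQuadripartiteStructureError
from .structure import PlastomeSequence, canonicalize, detect_inverted_repeats, \
    normalize_ssc_orientation
from .synthetic import (
    ContigSet,
    ErrorModel,
    Q8_ERROR_MODEL,
    Q9_ERROR_MODEL,
    SimulationConfig,
    TruthGenome,
    make_quality_tier_pair,
    simulate_plastome,
)


@dataclass
class PipelineResult:
    truth: TruthGenome
    tier_hi: ContigSet
    tier_lo: ContigSet
    consensus_hi: ConsensusAssembly
    consensus_lo: ConsensusAssembly
    reconciled: ConsensusAssembly
    resolutions: list[ResolutionRecord]
    assembly: PlastomeSequence  # reconciled, structurally normalized
    report_vs_truth: ComparisonReport
    diffs_vs_truth: list[DifferenceRecord]
    shared_gaps: SharedGapReport
    diffs_hi: list[DifferenceRecord] = field(default_factory=list)
    diffs_lo: list[DifferenceRecord] = field(default_factory=list)


def run_pipeline(sim_config: SimulationConfig | None = None,
                 model_hi: ErrorModel = Q8_ERROR_MODEL,
                 model_lo: ErrorModel = Q9_ERROR_MODEL,
                 seed: int = 0,
                 n_contigs: int = 3,
                 min_overlap: int = 2000,
                 revcomp_fraction: float = 0.5,
                 min_contig_len: int | None = None,
                 min_ir_len: int | None = None,
                 normalize_structure: bool = True) -> PipelineResult:
    """Run the full synthetic study: returns every intermediate artifact.

    ``min_contig_len`` defaults to 50 kb but is reduced automatically for
    small simulated genomes (a quarter of the genome length, if smaller);
    ``min_ir_len`` likewise defaults to min(1000, ir_len // 2).
    """
    cfg = sim_config or SimulationConfig(rng_seed=seed)
    truth = simulate_plastome(cfg)
    n = len(truth.sequence)
    if min_contig_len is None:
        min_contig_len = min(50_000, n // 4)
    if min_ir_len is None:
        min_ir_len = min(1000, cfg.ir_len // 2)

    tier_hi, tier_lo = make_quality_tier_pair(
        truth, model_hi, model_lo, seed=seed, n_contigs=n_contigs,
        min_overlap=min_overlap, revcomp_fraction=revcomp_fraction)

    reference = PlastomeSequence(id="truth", sequence=truth.sequence,
                                 circular=True, partition=truth.partition)
    cons_hi = assemble_tier(tier_hi, reference, min_len=min_contig_len)
    cons_lo = assemble_tier(tier_lo, reference, min_len=min_contig_len)
    reconciled, resolutions = reconcile_consensuses(cons_hi, cons_lo)

    assembly = PlastomeSequence(id="reconciled", sequence=reconciled.sequence,
                                circular=True)
    if normalize_structure:
        try:
            part = detect_inverted_repeats(assembly, min_ir_len=min_ir_len)
            assembly = canonicalize(assembly, part)
            assembly = normalize_ssc_orientation(assembly, assembly.partition,
                                                 reference)
        except NoQuadripartiteStructureError:
            pass  # degraded assembly without a detectable IR: leave as-is

    report = comparison_report(reference, assembly)
    aln = global_banded_align(reference.sequence, assembly.sequence)
    diffs = classify_differences(aln, frame_id=reference.id)

    aln_hi = global_banded_align(reference.sequence, cons_hi.sequence)
    aln_lo = global_banded_align(reference.sequence, cons_lo.sequence)
    diffs_hi = classify_differences(aln_hi, frame_id=reference.id)
    diffs_lo = classify_differences(aln_lo, frame_id=reference.id)
    shared = shared_gap_stats(diffs_hi, diffs_lo)

    return PipelineResult(
        truth=truth, tier_hi=tier_hi, tier_lo=tier_lo,
        consensus_hi=cons_hi, consensus_lo=cons_lo,
        reconciled=reconciled, resolutions=resolutions,
        assembly=assembly, report_vs_truth=report, diffs_vs_truth=diffs,
        shared_gaps=shared, diffs_hi=diffs_hi, diffs_lo=diffs_lo)
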