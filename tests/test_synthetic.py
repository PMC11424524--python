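"""Generator correctness: geometry, determinism, error model, fragmentation."""

import numpy as np
import pytest
from scipy import stats

from plastrecon import (
    ContigSet,
    ErrorModel,
    SimulationConfig,
    apply_ont_errors,
    fragment_into_contigs,
    make_quality_tier_pair,
    simulate_plastome,
)
from plastrecon._seq import maximal_runs, revcomp, wrap_slice
from plastrecon.errors import ConfigError

ZERO = ErrorModel(p_sub=0.0, p_del_base=0.0, p_del_slope=0.0)


class TestSimulatePlastome:
    def test_total_length_matches_quadripartite_sum(self):
        g = simulate_plastome(SimulationConfig(lsc_len=83_721, ssc_len=18_241,
                                               ir_len=25_044))
        assert len(g.sequence) == 152_050
        assert g.partition.total_len == 152_050

    def test_same_seed_is_deterministic(self):
        cfg = SimulationConfig(lsc_len=1000, ssc_len=200, ir_len=300, rng_seed=1)
        assert simulate_plastome(cfg).sequence == simulate_plastome(cfg).sequence

    @pytest.mark.parametrize("seed", range(5))
    def test_ira_is_reverse_complement_of_irb(self, seed):
        g = simulate_plastome(SimulationConfig(lsc_len=1500, ssc_len=400,
                                               ir_len=600, rng_seed=seed))
        assert g.region("ira") == revcomp(g.region("irb"))

    def test_partition_tiles_sequence(self, small_genome):
        p = small_genome.partition
        assert p.lsc[1] == p.irb[0]
        assert p.irb[1] == p.ssc[0]
        assert p.ssc[1] == p.ira[0]
        assert p.ira[1] == len(small_genome.sequence)

    def test_planted_runs_present_in_sequence(self, small_genome):
        s = small_genome.sequence
        # junction guards may clip a run start; require the bulk to be intact
        intact = sum(s[pos : pos + ln] == base * ln
                     for pos, base, ln in small_genome.planted_runs)
        assert intact >= 0.9 * len(small_genome.planted_runs)
        assert any(ln >= 4 for _, _, ln in small_genome.planted_runs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(lsc_len=0, ssc_len=10, ir_len=10)
        with pytest.raises(ConfigError):
            SimulationConfig(gc_fraction=1.5)


class TestApplyOntErrors:
    def test_zero_rates_identity(self, small_genome):
        out, log = apply_ont_errors(small_genome.sequence, ZERO, seed=3)
        assert out == small_genome.sequence
        assert log.events == []

    def test_log_replay_reproduces_output(self, small_genome):
        model = ErrorModel(p_sub=0.005, p_del_base=0.02, p_del_slope=0.05)
        for seed in range(5):
            out, log = apply_ont_errors(small_genome.sequence, model, seed=seed)
            assert log.replay(small_genome.sequence) == out

    def test_deletions_confined_to_homonucleotide_runs(self, small_genome):
        model = ErrorModel(p_sub=0.0, p_del_base=0.05, p_del_slope=0.05)
        seq = small_genome.sequence
        runs = {start: (length, base) for start, length, base in
                [(s, l, b) for s, l, b in maximal_runs(seq)]}
        out, log = apply_ont_errors(seq, model, seed=9)
        dels = [e for e in log.events if e.kind == "deletion"]
        assert dels, "expected deletions at these rates"
        for ev in dels:
            length, base = runs[ev.position]
            assert length >= 2
            assert int(ev.detail) <= min(length, model.max_del_len)
            assert set(seq[ev.position : ev.position + int(ev.detail)]) == {base}

    def test_positions_strictly_increasing_and_spans_disjoint(self, small_genome):
        model = ErrorModel(p_sub=0.01, p_del_base=0.05, p_del_slope=0.05)
        _, log = apply_ont_errors(small_genome.sequence, model, seed=4)
        end = -1
        for ev in log.events:
            assert ev.position > end
            if ev.kind == "deletion":
                end = ev.position + int(ev.detail) - 1
            else:
                end = ev.position

    def test_at_miscalls_below_uniform_share(self, rng):
        """A<->T substitutions are down-weighted relative to the uniform
        alternative draw; compare the observed count with the analytic
        expectation under the model definition."""
        from conftest import random_dna
        seq = random_dna(rng, 20_000, gc=0.5)
        w, p_sub = 0.2, 0.01
        model = ErrorModel(p_sub=p_sub, at_miscall_weight=w,
                           p_del_base=0.0, p_del_slope=0.0)
        n_at = n_total = 0
        for seed in range(40):
            _, log = apply_ont_errors(seq, model, seed=seed)
            for ev in log.events:
                n_total += 1
                orig = seq[ev.position]
                if {orig, str(ev.detail)} == {"A", "T"}:
                    n_at += 1
        f_at = (seq.count("A") + seq.count("T")) / len(seq)
        # per A/T base: alt=partner w.p. 1/3, retained w.p. w
        exp_at = 40 * len(seq) * f_at * p_sub * w / 3
        sd = np.sqrt(exp_at)
        uniform_at = 40 * len(seq) * f_at * p_sub / 3
        assert n_at < uniform_at * 0.5  # far below the uniform expectation
        assert abs(n_at - exp_at) < 5 * sd

    def test_homopolymer_attracts_more_deletions_than_mixed(self):
        model = ErrorModel(p_sub=0.0, p_del_base=0.05, p_del_slope=0.05)
        mean_homo = np.mean([
            len(apply_ont_errors("AAAAAAAA", model, s)[1].events)
            for s in range(300)])
        mean_mixed = np.mean([
            len(apply_ont_errors("ACGTACGT", model, s)[1].events)
            for s in range(300)])
        assert mean_homo > mean_mixed

    def test_deletion_rate_increases_with_run_length(self):
        """Rank correlation of (run length, deletion count) is positive."""
        spacer = "ACGTGCAT"
        lengths = list(range(2, 11))
        seq = spacer + spacer.join("C" * L if L % 2 else "G" * L
                                   for L in lengths) + spacer
        starts = []
        pos = len(spacer)
        for L in lengths:
            starts.append(pos)
            pos += L + len(spacer)
        model = ErrorModel(p_sub=0.0, p_del_base=0.01, p_del_slope=0.04)
        counts = {L: 0 for L in lengths}
        for seed in range(1000):
            _, log = apply_ont_errors(seq, model, seed)
            for ev in log.events:
                for st, L in zip(starts, lengths):
                    if st <= ev.position < st + L:
                        counts[L] += 1
        rho, _ = stats.spearmanr(lengths, [counts[L] for L in lengths])
        assert rho > 0


class TestFragmentIntoContigs:
    def test_single_contig_equals_linearized_input(self, small_genome):
        cs = fragment_into_contigs(small_genome.sequence, 1)
        assert len(cs) == 1
        assert cs.contigs[0].sequence == small_genome.sequence

    @pytest.mark.parametrize("n_contigs", [2, 3, 5])
    def test_contigs_cover_the_circle_with_overlap(self, small_genome, n_contigs):
        seq = small_genome.sequence
        n = len(seq)
        cs = fragment_into_contigs(seq, n_contigs, min_overlap=120, seed=8)
        covered = np.zeros(n, dtype=bool)  # interval-union oracle
        for c in cs:
            s, e = c.truth_interval
            for p in range(s, e):
                covered[p % n] = True
        assert covered.all()
        # adjacent contigs overlap by >= min_overlap
        ivs = sorted(c.truth_interval for c in cs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 - s2 >= 120
        assert ivs[-1][1] - n - ivs[0][0] >= 120  # wrap overlap

    def test_contig_sequences_match_truth_slices(self, small_genome):
        seq = small_genome.sequence
        for frac, seed in ((0.0, 1), (1.0, 2)):
            cs = fragment_into_contigs(seq, 3, min_overlap=100,
                                       revcomp_fraction=frac, seed=seed)
            for c in cs:
                sl = wrap_slice(seq, c.truth_interval[0], c.truth_interval[1])
                expected = revcomp(sl) if frac == 1.0 else sl
                assert c.strand == ("-" if frac == 1.0 else "+")
                assert c.sequence == expected

    def test_infeasible_geometry_raises(self, small_genome):
        with pytest.raises(ConfigError, match="min_overlap"):
            fragment_into_contigs(small_genome.sequence, 4, min_overlap=2000)
        with pytest.raises(ConfigError, match="min_len"):
            fragment_into_contigs(small_genome.sequence, 8, min_overlap=100,
                                  min_len=5000)


class TestQualityTierPair:
    def test_same_seed_identical_pair(self, small_genome):
        kw = dict(n_contigs=2, min_overlap=300)
        a1, b1 = make_quality_tier_pair(small_genome, seed=5, **kw)
        a2, b2 = make_quality_tier_pair(small_genome, seed=5, **kw)
        assert [c.sequence for c in a1] == [c.sequence for c in a2]
        assert [c.sequence for c in b1] == [c.sequence for c in b2]

    def test_model_ordering_enforced(self, small_genome):
        hi = ErrorModel(p_sub=0.001)
        lo = ErrorModel(p_sub=0.002)
        with pytest.raises(ConfigError):
            make_quality_tier_pair(small_genome, hi, lo, seed=0,
                                   n_contigs=2, min_overlap=300)

    def test_substitution_rate_ratio_tracks_models(self, small_genome):
        """hi p_sub twice lo p_sub -> substitution counts in a ~2:1 ratio."""
        hi = ErrorModel(p_sub=0.002, at_miscall_weight=1.0,
                        p_del_base=0.0, p_del_slope=0.0)
        lo = ErrorModel(p_sub=0.001, at_miscall_weight=1.0,
                        p_del_base=0.0, p_del_slope=0.0)
        n_hi = n_lo = 0
        for seed in range(150):
            a, b = make_quality_tier_pair(small_genome, hi, lo, seed=seed,
                                          n_contigs=2, min_overlap=300)
            n_hi += len(a.error_log.events)
            n_lo += len(b.error_log.events)
        ratio = n_hi / n_lo
        assert 1.7 < ratio < 2.3

    def test_tier_logs_are_in_truth_coordinates(self, small_genome):
        model = ErrorModel(p_sub=0.01, at_miscall_weight=1.0,
                           p_del_base=0.0, p_del_slope=0.0)
        tier, _ = make_quality_tier_pair(small_genome, model, model, seed=2,
                                         n_contigs=2, min_overlap=300,
                                         revcomp_fraction=1.0)
        truth = small_genome.sequence
        for ev in tier.error_log.events:
            if ev.kind == "substitution":
                assert str(ev.detail) != truth[ev.position]


class TestContigSetValidation:
    def test_duplicate_ids_rejected(self, small_genome):
        from plastrecon import Contig
        c = Contig("x", "ACGT", (0, 4), "+")
        with pytest.raises(ConfigError):
            ContigSet([c, c])
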