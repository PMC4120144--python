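import numpy as np
import pytest

from ranmap.align import (
    ALIGNED,
    AMBIGUOUS,
    UNALIGNED,
    align_all,
    align_read,
    extend_seed,
)
from ranmap.edit import bound_edit_distance, full_edit_distance
from ranmap.fm import build_index_pair
from ranmap.io import Genome, Read, reverse_complement
from ranmap.params import AlignerParams, derive_parameters
from ranmap.seeding import SeedMatch
from ranmap.simulate import SimConfig, random_genome, simulate


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def substituted(seq, pos):
    return seq[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]] + seq[pos + 1 :]


class TestExtendSeed:
    def test_full_length_seed_zero_distance(self, small_genome):
        r = small_genome.sequence[500:560]
        seed = SeedMatch(read_i=1, read_j=60, genome_start=500, length=60)
        cand = extend_seed(seed, r, small_genome, t=5)
        assert cand.dist == 0
        assert (cand.genome_start, cand.genome_end) == (500, 560)

    def test_substitution_in_left_flank(self, small_genome):
        r = substituted(small_genome.sequence[500:560], 5)
        # seed covers read[11..60]
        seed = SeedMatch(read_i=11, read_j=60, genome_start=510, length=50)
        cand = extend_seed(seed, r, small_genome, t=5)
        assert cand is not None
        assert cand.dist_left == 1 and cand.dist_right == 0 and cand.dist == 1

    def test_flank_over_budget_rejected(self, small_genome):
        t = 2
        r = small_genome.sequence[500:560]
        for pos in (0, 2, 4):  # t+1 substitutions in the left flank
            r = substituted(r, pos)
        seed = SeedMatch(read_i=11, read_j=60, genome_start=510, length=50)
        assert extend_seed(seed, r, small_genome, t=t) is None

    def test_genome_overhang_costs_missing_bases(self, small_genome):
        # seed at genome start, read has 3 flank bases hanging off the edge
        r = "TTT" + small_genome.sequence[0:40]
        seed = SeedMatch(read_i=4, read_j=43, genome_start=0, length=40)
        cand = extend_seed(seed, r, small_genome, t=5)
        assert cand is not None
        assert cand.dist_left >= 3  # one edit per missing base at least
        assert cand.genome_start == 0


class TestAlignRead:
    def test_error_free_unique_read(self, bench_genome, bench_pair):
        r = Read("r0", bench_genome.sequence[4321 : 4321 + 100])
        params = derive_parameters(100, 0.02)
        res = align_read(r, bench_pair, params, np.random.default_rng(0))
        assert res.status == ALIGNED
        assert res.attempts_used == 1
        assert res.chosen.dist == 0
        assert res.chosen.genome_start == 4321
        assert res.chosen.strand == "+"

    def test_reverse_strand_read(self, bench_genome, bench_pair):
        seg = bench_genome.sequence[7000:7100]
        r = Read("rc", reverse_complement(seg))
        params = derive_parameters(100, 0.02)
        res = align_read(r, bench_pair, params, np.random.default_rng(0))
        assert res.status == ALIGNED
        assert res.chosen.strand == "-"
        assert res.chosen.genome_start == 7000

    def test_triplicated_region_is_ambiguous(self):
        rng = np.random.default_rng(55)
        unit = random_dna(rng, 300)
        S = random_dna(rng, 500) + unit + random_dna(rng, 400) + unit \
            + random_dna(rng, 400) + unit + random_dna(rng, 500)
        pair = build_index_pair(Genome("rep", S))
        r = Read("r", unit[100:200])
        params = derive_parameters(100, 0.02)
        res = align_read(r, pair, params, np.random.default_rng(1))
        assert res.status == AMBIGUOUS

    def test_unrelated_read_unaligned(self, bench_pair):
        rng = np.random.default_rng(1234)
        r = Read("junk", random_dna(rng, 100))
        params = derive_parameters(100, 0.02)
        res = align_read(r, bench_pair, params, np.random.default_rng(2))
        assert res.status == UNALIGNED
        assert res.attempts_used == params.A

    def test_aligned_results_pass_distance_recheck(self, bench_genome, bench_pair):
        """Every accepted alignment is within the budget by the full DP."""
        cfg = SimConfig(n_reads=60, read_length=100, rng_seed=3)
        reads, _, _ = simulate(bench_genome, cfg)
        params = derive_parameters(100, 0.02)
        n_checked = 0
        for res in align_all(reads, bench_pair, params=params, rng_seed=3):
            if res.status != ALIGNED:
                continue
            c = res.chosen
            seq = res.read_sequence
            if c.strand == "-":
                seq = reverse_complement(seq)
            window = bench_genome.sequence[c.genome_start : c.genome_end]
            assert full_edit_distance(seq, window) <= params.t
            n_checked += 1
        assert n_checked >= 50

    def test_recall_non_decreasing_in_attempts(self, bench_genome, bench_pair):
        """More attempts never un-align a read (per-read RNG held fixed)."""
        cfg = SimConfig(n_reads=120, read_length=100, base_error_rate=0.04, rng_seed=9)
        reads, _, _ = simulate(bench_genome, cfg)
        base = derive_parameters(100, 0.04)
        aligned_at = {}
        for a in (1, 3, base.A):
            params = derive_parameters(100, 0.04, a_override=a)
            aligned_at[a] = {
                r.read_id
                for r in align_all(reads, bench_pair, params=params, rng_seed=9)
                if r.status == ALIGNED
            }
        assert aligned_at[1] <= aligned_at[3] <= aligned_at[base.A]


class TestAlignAll:
    def test_deterministic_given_seed(self, bench_genome, bench_pair):
        cfg = SimConfig(n_reads=40, read_length=100, rng_seed=4)
        reads, _, _ = simulate(bench_genome, cfg)

        def run():
            return [
                (r.status, r.chosen.genome_start if r.chosen else None)
                for r in align_all(reads, bench_pair, rng_seed=7)
            ]

        assert run() == run()

    def test_batch_order_independent(self, bench_genome, bench_pair):
        """Per-read substreams: permuting read order preserves per-read results."""
        cfg = SimConfig(n_reads=30, read_length=100, base_error_rate=0.04, rng_seed=6)
        reads, _, _ = simulate(bench_genome, cfg)
        params = derive_parameters(100, 0.04)
        fwd = list(align_all(reads, bench_pair, params=params, rng_seed=5))
        # reversed batch, but substreams keyed by original ordinal
        rng_by_id = {r.id: np.random.default_rng((5, i)) for i, r in enumerate(reads)}
        rev = {
            r.id: align_read(r, bench_pair, params, rng_by_id[r.id])
            for r in reversed(reads)
        }
        for res in fwd:
            other = rev[res.read_id]
            assert res.status == other.status
            if res.status == ALIGNED:
                assert res.chosen.genome_start == other.chosen.genome_start

    def test_error_free_reads_align_at_truth(self, bench_genome, bench_pair):
        """>= 99% of 1000 noise-free reads align, each at its true locus."""
        from ranmap.io import parse_truth_name

        cfg = SimConfig(
            n_reads=1000, read_length=100,
            base_error_rate=0.0, mutation_rate=0.0, rng_seed=10,
        )
        reads, _, _ = simulate(bench_genome, cfg)
        results = list(align_all(reads, bench_pair, b=0.0, rng_seed=10))
        aligned = [r for r in results if r.status == ALIGNED]
        assert len(aligned) >= 990
        for res in aligned:
            truth, _ = parse_truth_name(res.read_id)
            assert res.chosen.genome_start + 1 == truth.start
            assert res.chosen.strand == truth.strand
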