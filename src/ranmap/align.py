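"""Randomized seed-and-extend alignment of reads.

Each read gets up to A attempts. Attempt 1 anchors at p = 1 (the
wrap-around case); later attempts draw p uniformly from {1..m}. Every seed
found at p is extended by computing the edit distance of the two read
flanks against the genome stretches adjoining the seed, with the pruned
bound and budget t. An attempt that yields one or two distinct candidates
aligns the read; three or more is an ambiguity failure (likely a repeat);
A fruitless attempts leave the read unaligned.

Both strands are always tried: the reverse complement of the read is
aligned with the same machinery and candidates from the two orientations
are pooled within an attempt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .edit import bound_edit_distance
from .fm import FMIndexPair
from .io import Genome, Read, reverse_complement
from .params import AlignerParams, derive_parameters
from .seeding import SeedMatch, common_substrings, wraparound_seeds

logger = logging.getLogger(__name__)

ALIGNED = "ALIGNED"
AMBIGUOUS = "AMBIGUOUS"
UNALIGNED = "UNALIGNED"


@dataclass(frozen=True)
class CandidateAlignment:
    """A seed extended to a full-read placement with edit distance <= t."""

    genome_start: int        # 0-based start of s_L + s + s_R
    genome_end: int          # 0-based exclusive end
    dist: int
    dist_left: int
    dist_right: int
    strand: str
    seed: SeedMatch


@dataclass
class AlignmentResult:
    read_id: str
    read_sequence: str
    status: str
    candidates: list[CandidateAlignment] = field(default_factory=list)
    attempts_used: int = 0

    @property
    def chosen(self) -> Optional[CandidateAlignment]:
        return self.candidates[0] if self.status == ALIGNED else None


def extend_seed(
    seed: SeedMatch, read_seq: str, genome: Genome, t: int
) -> Optional[CandidateAlignment]:
    """Extend one seed to a candidate, or None when the budget t is blown.

    For an ordinary seed matching read[i..j], the left flank read[1..i-1]
    is compared against the (i-1)-length genome stretch preceding the seed
    and the right flank read[j+1..m] against the (m-j)-length stretch
    following it; the right comparison runs on the budget left over from
    the left. Genome overhang shows up as a length deficit, which the DP
    charges one edit per missing base. For a wrapped seed the two matched
    blocks pin both read ends and the flank is the gap interior between
    them.
    """
    S = genome.sequence
    n = len(S)
    m = len(read_seq)
    if seed.wrapped:
        fl = min(seed.prefix_len, m - seed.suffix_len)
        mid_read = read_seq[fl : m - seed.suffix_len]
        g_lo = seed.genome_start + fl
        g_hi = seed.genome_end + 1 - seed.suffix_len
        overlap = max(0, g_lo - g_hi)
        verdict = bound_edit_distance(mid_read, S[g_lo : max(g_lo, g_hi)], t)
        dist = verdict.value + overlap
        if verdict.exceeded or dist > t:
            return None
        return CandidateAlignment(
            genome_start=seed.genome_start,
            genome_end=seed.genome_end + 1,
            dist=dist,
            dist_left=dist,
            dist_right=0,
            strand="+",
            seed=seed,
        )
    i, j = seed.read_i, seed.read_j
    left_read = read_seq[: i - 1]
    left_lo = seed.genome_start - (i - 1)
    s_left = S[max(0, left_lo) : seed.genome_start]
    lv = bound_edit_distance(left_read, s_left, t)
    if lv.exceeded:
        return None
    budget = t - lv.value
    right_read = read_seq[j:]
    right_lo = seed.genome_start + seed.length
    s_right = S[right_lo : min(n, right_lo + (m - j))]
    rv = bound_edit_distance(right_read, s_right, budget)
    if rv.exceeded:
        return None
    return CandidateAlignment(
        genome_start=max(0, left_lo),
        genome_end=min(n, right_lo + (m - j)),
        dist=lv.value + rv.value,
        dist_left=lv.value,
        dist_right=rv.value,
        strand="+",
        seed=seed,
    )


def _candidate_order(c: CandidateAlignment) -> tuple:
    # primary pick: lowest distance, then leftmost, then + strand
    return (c.dist, c.genome_start, 0 if c.strand == "+" else 1)


def align_read(
    read: Read, pair: FMIndexPair, params: AlignerParams, rng: np.random.Generator
) -> AlignmentResult:
    """Align one read: A randomized attempts, two-candidate ambiguity rule."""
    m = len(read)
    fwd = read.sequence
    rev = reverse_complement(fwd)
    genome = pair.genome
    for attempt in range(1, params.A + 1):
        p = 1 if attempt == 1 else int(rng.integers(1, m + 1))
        by_locus: dict[tuple[int, str], CandidateAlignment] = {}
        for strand, seq in (("+", fwd), ("-", rev)):
            if p == 1:
                seeds = wraparound_seeds(pair, seq, params)
            else:
                seeds = common_substrings(pair, seq, p, params)
            for seed in seeds:
                cand = extend_seed(seed, seq, genome, params.t)
                if cand is None:
                    continue
                if strand == "-":
                    cand = CandidateAlignment(
                        genome_start=cand.genome_start,
                        genome_end=cand.genome_end,
                        dist=cand.dist,
                        dist_left=cand.dist_left,
                        dist_right=cand.dist_right,
                        strand="-",
                        seed=seed,
                    )
                key = (cand.genome_start, cand.strand)
                prev = by_locus.get(key)
                if prev is None or cand.dist < prev.dist:
                    by_locus[key] = cand
        if by_locus:
            cands = sorted(by_locus.values(), key=_candidate_order)
            if len(cands) > 2:
                return AlignmentResult(read.id, fwd, AMBIGUOUS, [], attempt)
            return AlignmentResult(read.id, fwd, ALIGNED, cands, attempt)
    return AlignmentResult(read.id, fwd, UNALIGNED, [], params.A)


def align_all(
    reads: Iterable[Read],
    pair: FMIndexPair,
    params: Optional[AlignerParams] = None,
    b: float = 0.02,
    c_sigma: float = 4.0,
    a_multiplier: int = 1,
    max_hits: int = 100,
    rng_seed: int = 0,
    **derive_kwargs,
) -> Iterator[AlignmentResult]:
    """Align a stream of reads with per-read reproducible RNG substreams.

    Each read's generator is seeded from (rng_seed, ordinal), so results do
    not depend on batching and a permuted input yields identical per-read
    outcomes. When ``params`` is None, parameters are derived per read
    length (cached) from b and c_sigma.
    """
    cache: dict[int, AlignerParams] = {}
    tallies = {ALIGNED: 0, AMBIGUOUS: 0, UNALIGNED: 0}
    for ordinal, read in enumerate(reads):
        if params is not None:
            pr = params
        else:
            m = len(read)
            if m not in cache:
                cache[m] = derive_parameters(
                    m, b, c_sigma, a_multiplier, max_hits,
                    rng_seed=rng_seed, **derive_kwargs,
                )
            pr = cache[m]
        rng = np.random.default_rng((rng_seed, ordinal))
        res = align_read(read, pair, pr, rng)
        tallies[res.status] += 1
        yield res
    logger.info(
        "aligned=%d ambiguous=%d unaligned=%d",
        tallies[ALIGNED], tallies[AMBIGUOUS], tallies[UNALIGNED],
    )
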