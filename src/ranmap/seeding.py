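"""Common substrings of a read and the genome, anchored at a read position.

Given a read position p, the longest substring of the read that passes
through p and occurs exactly in the genome is the concatenation b + f of
the maximal backward match ending just left of p and the maximal forward
match starting at p. Each (b-occurrence, f-occurrence) pair that is
contiguous in the genome yields one seed; seeds shorter than W are
discarded.

The p = 1 case treats the read as circular: b becomes a suffix of the read
and f a prefix, matching at two genome loci separated by a gap. Pairs whose
genome span differs from the read length by more than the distance budget t
are rejected.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .fm import FMIndexPair, maximal_backward_match, maximal_forward_match
from .params import AlignerParams


@dataclass(frozen=True)
class SeedMatch:
    """An exact common substring of read and genome.

    ``read_i``/``read_j`` are 1-based inclusive read coordinates;
    ``genome_start`` is 0-based. For wrapped seeds the read prefix of
    length ``prefix_len`` matches at ``genome_start`` and the read suffix
    of length ``suffix_len`` ends at ``genome_end`` (0-based inclusive);
    ``length`` is always the total matched length.
    """

    read_i: int
    read_j: int
    genome_start: int
    length: int
    wrapped: bool = False
    prefix_len: int = 0
    suffix_len: int = 0
    genome_end: int = -1


def common_substrings(
    pair: FMIndexPair, read_seq: str, p: int, params: AlignerParams
) -> list[SeedMatch]:
    """Seeds through read position p (1-based, 2 <= p <= m).

    The backward match covers read[..p-1], the forward match read[p..];
    occurrence pairs adjacent in the genome (b ends at q-1 where f starts
    at q) merge into one seed. When one side has no match at all, the other
    side alone is a candidate seed, still subject to length >= W.
    """
    m = len(read_seq)
    if not (2 <= p <= m):
        raise ValueError(f"p={p} out of range [2, {m}]")
    len_b, b_ends = maximal_backward_match(pair, read_seq, p, params.max_hits)
    len_f, f_starts = maximal_forward_match(pair, read_seq, p, params.max_hits)
    seeds: list[SeedMatch] = []
    if len_b == 0 and len_f == 0:
        return seeds
    if len_b == 0:
        if len_f >= params.W:
            seeds = [
                SeedMatch(read_i=p, read_j=p + len_f - 1, genome_start=q, length=len_f)
                for q in f_starts
            ]
        return seeds
    if len_f == 0:
        if len_b >= params.W:
            seeds = [
                SeedMatch(
                    read_i=p - len_b,
                    read_j=p - 1,
                    genome_start=e - len_b + 1,
                    length=len_b,
                )
                for e in b_ends
            ]
        return seeds
    if len_b + len_f < params.W:
        return seeds
    b_end_set = set(b_ends)
    for q in f_starts:
        if q - 1 in b_end_set:
            seeds.append(
                SeedMatch(
                    read_i=p - len_b,
                    read_j=p + len_f - 1,
                    genome_start=q - len_b,
                    length=len_b + len_f,
                )
            )
    return seeds


def wraparound_seeds(
    pair: FMIndexPair, read_seq: str, params: AlignerParams
) -> list[SeedMatch]:
    """Seeds for p = 1: maximal read prefix + maximal read suffix.

    Prefix occurrences at q_f pair with suffix occurrences ending at
    q_b_end when |(q_b_end - q_f + 1) - m| <= t, i.e. the two loci span
    roughly one read length. An exact whole-read match short-circuits to
    ordinary full-length seeds. A prefix or suffix that alone reaches
    length >= W is also returned as an ordinary seed.
    """
    m = len(read_seq)
    t, W = params.t, params.W
    len_f, f_starts = maximal_forward_match(pair, read_seq, 1, params.max_hits)
    if len_f == m:
        return [
            SeedMatch(read_i=1, read_j=m, genome_start=q, length=m) for q in f_starts
        ]
    # maximal suffix of the whole read: backward match with p just past the end
    len_b, b_ends = maximal_backward_match(pair, read_seq, m + 1, params.max_hits)
    seeds: list[SeedMatch] = []
    if len_f >= W:
        seeds.extend(
            SeedMatch(read_i=1, read_j=len_f, genome_start=q, length=len_f)
            for q in f_starts
        )
    if len_b >= W:
        seeds.extend(
            SeedMatch(
                read_i=m - len_b + 1,
                read_j=m,
                genome_start=e - len_b + 1,
                length=len_b,
            )
            for e in b_ends
        )
    if len_f > 0 and len_b > 0 and len_f + len_b >= W:
        b_sorted = sorted(b_ends)
        for q_f in f_starts:
            lo = bisect_left(b_sorted, q_f + m - 1 - t)
            hi = bisect_right(b_sorted, q_f + m - 1 + t)
            for q_b_end in b_sorted[lo:hi]:
                if q_b_end < q_f:
                    continue
                seeds.append(
                    SeedMatch(
                        read_i=1,
                        read_j=m,
                        genome_start=q_f,
                        length=len_f + len_b,
                        wrapped=True,
                        prefix_len=len_f,
                        suffix_len=len_b,
                        genome_end=q_b_end,
                    )
                )
    return _dedup(seeds)


def _dedup(seeds: list[SeedMatch]) -> list[SeedMatch]:
    seen: set[SeedMatch] = set()
    out = []
    for s in seeds:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out
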