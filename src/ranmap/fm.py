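"""FM indices over the reference genome and its reverse.

Two indices drive bidirectional exact matching: the *backward* index is
built on the genome S itself and extends matches leftward in the read; the
*forward* index is built on reverse(S), where a backward search is
equivalent to extending rightward in S. Together they find, for any read
position p, the longest substring of the read through p that occurs
exactly in S.

The sentinel $ is appended internally and sorts before every nucleotide;
N is kept in the text (coordinates are preserved) but never matches during
search, so seeds cannot span N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Genome

# Lexicographic codes. $ < A < C < G < N < T (ASCII order of ACGNT).
ALPHABET = "$ACGNT"
CODE = {c: i for i, c in enumerate(ALPHABET)}
_ENC = np.zeros(256, dtype=np.uint8)
for _c, _i in CODE.items():
    _ENC[ord(_c)] = _i
SENTINEL = 0
N_CODE = CODE["N"]
SEARCHABLE = frozenset("ACGT")


def _encode(text: str) -> np.ndarray:
    return _ENC[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort passes)."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        rank2[: n - k] = rank[k:]
        order = np.lexsort((rank2, rank))
        r, r2 = rank[order], rank2[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r[1:] != r[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


@dataclass(frozen=True)
class SAInterval:
    """Half-open row range [lo, hi) in the suffix array."""

    lo: int
    hi: int

    @property
    def size(self) -> int:
        return self.hi - self.lo

    @property
    def empty(self) -> bool:
        return self.hi <= self.lo


EMPTY_INTERVAL = SAInterval(0, 0)


@dataclass
class FMIndex:
    """FM index of one text: BWT, C array, full occ ranks, sampled SA."""

    text_length: int
    bwt: np.ndarray                      # uint8 codes, length text_length+1
    counts: np.ndarray                   # C[c] = # chars coded < c in text+$
    occ: np.ndarray                      # occ[c, i] = # of c in bwt[:i]
    sa_values: np.ndarray                # sampled SA values, -1 where unsampled
    sa_stride: int

    def full_interval(self) -> SAInterval:
        return SAInterval(0, self.text_length + 1)

    def extend_backward(self, interval: SAInterval, ch: str) -> SAInterval:
        """Narrow the interval by prepending one character to the pattern.

        Returns the empty interval for N (never matched) and for characters
        absent from the text.
        """
        if ch not in SEARCHABLE:
            return EMPTY_INTERVAL
        c = CODE[ch]
        lo = int(self.counts[c] + self.occ[c, interval.lo])
        hi = int(self.counts[c] + self.occ[c, interval.hi])
        return SAInterval(lo, hi) if lo < hi else EMPTY_INTERVAL

    def _lf(self, row: int) -> int:
        c = self.bwt[row]
        return int(self.counts[c] + self.occ[c, row])

    def _sa_at(self, row: int) -> int:
        steps = 0
        while self.sa_values[row] < 0:
            row = self._lf(row)
            steps += 1
        return (int(self.sa_values[row]) + steps) % (self.text_length + 1)

    def locate(self, interval: SAInterval, cap: int = 2**62) -> list[int]:
        """Text positions (0-based starts) for an interval, ascending, capped."""
        if interval.empty:
            return []
        if self.sa_stride == 1:
            pos = np.sort(self.sa_values[interval.lo : interval.hi])
            return [int(x) for x in pos[:cap]]
        pos = sorted(self._sa_at(row) for row in range(interval.lo, interval.hi))
        return pos[:cap]

    def search(self, pattern: str) -> SAInterval:
        """Backward search of a whole pattern; empty interval if absent."""
        interval = self.full_interval()
        for ch in reversed(pattern):
            interval = self.extend_backward(interval, ch)
            if interval.empty:
                return EMPTY_INTERVAL
        return interval

    def count(self, pattern: str) -> int:
        return self.search(pattern).size


def build_fm_index(text: str, sa_stride: Optional[int] = None) -> FMIndex:
    """Build the FM index of a nucleotide string (sentinel added internally).

    Full suffix-array retention (stride 1) below 1 Mb, stride 16 above,
    unless overridden.
    """
    if not text:
        raise ValueError("cannot index an empty text")
    n = len(text)
    if sa_stride is None:
        sa_stride = 1 if n < 1_000_000 else 16
    codes = np.empty(n + 1, dtype=np.uint8)
    codes[:n] = _encode(text)
    codes[n] = SENTINEL
    sa = _suffix_array(codes)
    bwt = codes[(sa - 1) % (n + 1)]
    # C array over the 6-letter coded alphabet
    hist = np.bincount(codes, minlength=len(ALPHABET))
    counts = np.zeros(len(ALPHABET), dtype=np.int64)
    counts[1:] = np.cumsum(hist)[:-1]
    # occ[c, i] = occurrences of code c in bwt[:i]
    occ = np.zeros((len(ALPHABET), n + 2), dtype=np.int64)
    for c in range(len(ALPHABET)):
        occ[c, 1:] = np.cumsum(bwt == c)
    if sa_stride == 1:
        sa_values = sa.copy()
    else:
        sa_values = np.where(sa % sa_stride == 0, sa, -1)
    return FMIndex(
        text_length=n,
        bwt=bwt,
        counts=counts,
        occ=occ,
        sa_values=sa_values,
        sa_stride=sa_stride,
    )


@dataclass
class FMIndexPair:
    """Backward index of S and forward index (index of reverse(S))."""

    backward: FMIndex
    forward: FMIndex
    genome: Genome


def build_index_pair(genome: Genome, sa_stride: Optional[int] = None) -> FMIndexPair:
    return FMIndexPair(
        backward=build_fm_index(genome.sequence, sa_stride),
        forward=build_fm_index(genome.sequence[::-1], sa_stride),
        genome=genome,
    )


def maximal_backward_match(
    pair: FMIndexPair, read_seq: str, p: int, max_hits: int = 100
) -> tuple[int, list[int]]:
    """Longest suffix of read[1..p-1] occurring in S, with its end positions.

    ``p`` is 1-based; characters are consumed right-to-left through the
    backward index. Returns (length, 0-based genome END positions of the
    match, ascending, capped at max_hits). Length 0 when p == 1 or the
    character just left of p occurs nowhere. p may be m+1, in which case
    the whole read's maximal suffix is matched (used by wrap-around
    seeding).
    """
    if not (1 <= p <= len(read_seq) + 1):
        raise ValueError(f"p={p} out of range for read of length {len(read_seq)}")
    idx = pair.backward
    interval = idx.full_interval()
    best: SAInterval = EMPTY_INTERVAL
    length = 0
    for i in range(p - 2, -1, -1):
        nxt = idx.extend_backward(interval, read_seq[i])
        if nxt.empty:
            break
        interval = nxt
        best = nxt
        length += 1
    if length == 0:
        return 0, []
    starts = idx.locate(best, cap=max_hits)
    return length, [s + length - 1 for s in starts]


def maximal_forward_match(
    pair: FMIndexPair, read_seq: str, p: int, max_hits: int = 100
) -> tuple[int, list[int]]:
    """Longest prefix of read[p..m] occurring in S, with its start positions.

    Searched backward in the index of reverse(S): consuming read characters
    left-to-right prepends them to the reversed pattern. An occurrence at
    position q in reverse(S) starts at |S| - q - length in S. Returns
    (length, 0-based genome START positions, ascending, capped).
    """
    if not (1 <= p <= len(read_seq)):
        raise ValueError(f"p={p} out of range for read of length {len(read_seq)}")
    idx = pair.forward
    n = idx.text_length
    interval = idx.full_interval()
    best: SAInterval = EMPTY_INTERVAL
    length = 0
    for i in range(p - 1, len(read_seq)):
        nxt = idx.extend_backward(interval, read_seq[i])
        if nxt.empty:
            break
        interval = nxt
        best = nxt
        length += 1
    if length == 0:
        return 0, []
    rev_starts = idx.locate(best, cap=max_hits)
    return length, sorted(n - q - length for q in rev_starts)


# ---------------------------------------------------------------------------
# persistence

_FORMAT_VERSION = 1


def save_index_pair(pair: FMIndexPair, prefix: str) -> str:
    """Persist both indices plus metadata as one .npz archive."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "genome_name": pair.genome.name,
        "genome_length": pair.genome.length,
    }
    arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for tag, idx in (("b", pair.backward), ("f", pair.forward)):
        arrays[f"{tag}_bwt"] = idx.bwt
        arrays[f"{tag}_counts"] = idx.counts
        arrays[f"{tag}_occ"] = idx.occ
        arrays[f"{tag}_sa"] = idx.sa_values
        arrays[f"{tag}_stride"] = np.array([idx.sa_stride, idx.text_length])
    path = f"{prefix}.fmidx.npz"
    np.savez_compressed(path, **arrays)
    return path


def load_index_pair(prefix: str, genome_sequence: Optional[str] = None) -> FMIndexPair:
    """Load an index archive; reconstructs the genome text from the BWT
    unless the sequence is supplied."""
    path = prefix if prefix.endswith(".fmidx.npz") else f"{prefix}.fmidx.npz"
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported index format {meta['format_version']}")
        indices = {}
        for tag in ("b", "f"):
            stride, text_length = (int(x) for x in data[f"{tag}_stride"])
            indices[tag] = FMIndex(
                text_length=text_length,
                bwt=data[f"{tag}_bwt"].copy(),
                counts=data[f"{tag}_counts"].copy(),
                occ=data[f"{tag}_occ"].copy(),
                sa_values=data[f"{tag}_sa"].copy(),
                sa_stride=stride,
            )
    if genome_sequence is None:
        genome_sequence = _invert_bwt(indices["b"])
    genome = Genome(name=meta["genome_name"], sequence=genome_sequence)
    return FMIndexPair(backward=indices["b"], forward=indices["f"], genome=genome)


def _invert_bwt(idx: FMIndex) -> str:
    """Recover the text by LF-walking from the sentinel row."""
    n = idx.text_length
    out = np.empty(n, dtype=np.uint8)
    row = 0  # row 0 is the sentinel-initial rotation; bwt[0] is the last char
    for i in range(n - 1, -1, -1):
        out[i] = idx.bwt[row]
        row = idx._lf(row)
    return "".join(ALPHABET[c] for c in out)
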