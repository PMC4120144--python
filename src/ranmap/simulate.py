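"""wgsim-style read simulation.

The reference is first mutated into a donor haplotype: each site
independently becomes a polymorphism with probability ``mutation_rate``;
85% of polymorphisms are SNPs (uniform over the three other bases) and 15%
are indels, insertion or deletion equiprobably, with lengths from the
geometric density 0.7 * 0.3^(l-1). Reads are then sampled uniformly from
either strand of the donor and each base is flipped to a uniformly chosen
different base with probability ``base_error_rate``. The true origin — the
REFERENCE-coordinate interval of the sampled donor segment and the strand —
is encoded in the read name, so downstream evaluation needs no side file.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .io import Genome, Read, TruthRecord, encode_truth_name, reverse_complement

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    n_reads: int
    read_length: int
    base_error_rate: float = 0.02
    mutation_rate: float = 0.001
    indel_fraction: float = 0.15
    indel_ext: float = 0.3       # geometric continuation; P(L=l) = 0.7 * 0.3^(l-1)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "mutation_rate", "indel_fraction", "indel_ext"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_reads < 1 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be >= 1")


@dataclass(frozen=True)
class VariantRecord:
    """A planted polymorphism, in 1-based reference coordinates."""

    position: int
    kind: str                 # SNP | INS | DEL
    ref_allele: str
    alt_allele: str


def random_genome(
    length: int, rng: np.random.Generator, name: str = "synthetic"
) -> Genome:
    """I.i.d. uniform ACGT genome (the repeat-poor null model)."""
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    return Genome(name=name, sequence=seq)


def _other_base(base: str, k: int) -> str:
    """k-th (0..2) base different from ``base``; any base for N."""
    if base not in BASES:
        return BASES[k]
    choices = BASES.replace(base, "")
    return choices[k]


def mutate_genome(
    genome: Genome, cfg: SimConfig, rng: np.random.Generator
) -> tuple[Genome, list[VariantRecord]]:
    """Plant polymorphisms, returning the donor haplotype and the variants."""
    seq = genome.sequence
    n = len(seq)
    if cfg.mutation_rate == 0.0:
        return genome, []
    is_poly = rng.random(n) < cfg.mutation_rate
    donor_parts: list[str] = []
    variants: list[VariantRecord] = []
    i = 0
    while i < n:
        if not is_poly[i]:
            donor_parts.append(seq[i])
            i += 1
            continue
        if rng.random() >= cfg.indel_fraction:
            alt = _other_base(seq[i], int(rng.integers(0, 3)))
            donor_parts.append(alt)
            variants.append(VariantRecord(i + 1, "SNP", seq[i], alt))
            i += 1
        else:
            length = int(rng.geometric(1.0 - cfg.indel_ext))
            if rng.random() < 0.5:
                ins = "".join(BASES[k] for k in rng.integers(0, 4, size=length))
                donor_parts.append(seq[i] + ins)
                variants.append(VariantRecord(i + 1, "INS", seq[i], seq[i] + ins))
                i += 1
            else:
                length = min(length, n - i)
                variants.append(VariantRecord(i + 1, "DEL", seq[i : i + length], ""))
                i += length
    donor = Genome(name=genome.name, sequence="".join(donor_parts))
    return donor, variants


def _coordinate_map(variants: list[VariantRecord]) -> tuple[list[int], list[int]]:
    """Donor->reference anchors: parallel sorted lists (donor_start, ref_start)
    of the copied/SNP blocks between indels."""
    donor_starts = [0]
    ref_starts = [0]
    d = r = 0
    for v in variants:
        if v.kind == "SNP":
            continue
        ref0 = v.position - 1
        d += ref0 - r
        r = ref0
        if v.kind == "INS":
            ins_len = len(v.alt_allele) - 1
            d += 1 + ins_len
            r += 1
        else:  # DEL
            r += len(v.ref_allele)
        donor_starts.append(d)
        ref_starts.append(r)
    return donor_starts, ref_starts


def donor_to_ref(
    donor_pos: int, donor_starts: list[int], ref_starts: list[int],
    variants: list[VariantRecord],
) -> int:
    """Reference coordinate (0-based) of a donor base.

    A base inside an insertion maps to the preceding reference base; the
    20-bp evaluation tolerance absorbs the resulting ambiguity.
    """
    idx = bisect_right(donor_starts, donor_pos) - 1
    off = donor_pos - donor_starts[idx]
    ref = ref_starts[idx] + off
    # clamp positions that fall inside the insertion preceding the next block
    if idx + 1 < len(donor_starts):
        ref = min(ref, max(ref_starts[idx], ref_starts[idx + 1] - 1))
    return ref


def sample_reads(
    donor: Genome,
    variants: list[VariantRecord],
    cfg: SimConfig,
    rng: np.random.Generator,
    source_name: Optional[str] = None,
) -> Iterator[Read]:
    """Sample reads from the donor with per-base errors and truth names."""
    m = cfg.read_length
    dn = donor.length
    if dn < m:
        raise ValueError(f"donor length {dn} shorter than read length {m}")
    donor_starts, ref_starts = _coordinate_map(variants)
    src = source_name if source_name is not None else donor.name
    for serial in range(cfg.n_reads):
        start = int(rng.integers(0, dn - m + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        seg = donor.sequence[start : start + m]
        if strand == "-":
            seg = reverse_complement(seg)
        if cfg.base_error_rate > 0.0:
            mask = rng.random(m) < cfg.base_error_rate
            if mask.any():
                chars = list(seg)
                picks = rng.integers(0, 3, size=int(mask.sum()))
                for pos, k in zip(np.flatnonzero(mask), picks):
                    chars[pos] = _other_base(chars[pos], int(k))
                seg = "".join(chars)
        ref_lo = donor_to_ref(start, donor_starts, ref_starts, variants)
        ref_hi = donor_to_ref(start + m - 1, donor_starts, ref_starts, variants)
        truth = TruthRecord(src, ref_lo + 1, ref_hi + 1, strand)
        yield Read(
            id=encode_truth_name(truth, serial),
            sequence=seg,
            qualities="I" * m,
        )


def simulate(
    genome: Genome, cfg: SimConfig
) -> tuple[list[Read], list[VariantRecord], Genome]:
    """Mutate + sample in one call; all randomness from cfg.rng_seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    donor, variants = mutate_genome(genome, cfg, rng)
    reads = list(sample_reads(donor, variants, cfg, rng, source_name=genome.name))
    return reads, variants, donor
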