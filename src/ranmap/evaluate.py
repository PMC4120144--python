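"""Alignment scoring against simulated truth, and genome repeat density.

A read counts as *aligned* when its primary SAM record is mapped, and as
*correct* when it is aligned on the truth strand within ``tolerance_bp``
(default 20) of the truth start position. From these,

    precision          = correct / aligned
    recall             = correct / total reads
    misalignment rate  = (aligned - correct) / total reads.

Repeat density D(S|k) is the fraction of k-mer windows of the genome whose
k-mer occurs at least twice — the probability that a random length-k read
drawn from S is a repeat, and hence a direct measure of how hard S is to
align to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam
from scipy import stats

from .io import Genome, TruthRecord, parse_truth_name


@dataclass(frozen=True)
class EvalReport:
    n_reads: int
    n_aligned: int
    n_correct: int
    tolerance_bp: int = 20

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_aligned if self.n_aligned else 0.0

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_reads if self.n_reads else 0.0

    @property
    def misalignment_rate(self) -> float:
        return (self.n_aligned - self.n_correct) / self.n_reads if self.n_reads else 0.0

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_aligned": self.n_aligned,
            "n_correct": self.n_correct,
            "precision": self.precision,
            "recall": self.recall,
            "misalignment_rate": self.misalignment_rate,
            "tolerance_bp": self.tolerance_bp,
        }


def _iter_primary(sam):
    if isinstance(sam, (str, bytes)) or hasattr(sam, "__fspath__"):
        with pysam.AlignmentFile(str(sam), "r") as fh:
            for rec in fh:
                if not rec.is_secondary and not rec.is_supplementary:
                    yield rec
    else:
        for rec in sam:
            if not rec.is_secondary and not rec.is_supplementary:
                yield rec


def evaluate(
    sam,
    truth: Optional[Mapping[str, TruthRecord]] = None,
    tolerance_bp: int = 20,
) -> EvalReport:
    """Score primary SAM records against truth.

    ``sam`` is a SAM path or an iterable of pysam records. When ``truth``
    is None the truth is parsed from the read names. A read is correct iff
    mapped, on the truth strand, and its 1-based leftmost position is
    within ``tolerance_bp`` of the truth start.
    """
    n_reads = n_aligned = n_correct = 0
    missing: list[str] = []
    for rec in _iter_primary(sam):
        n_reads += 1
        name = rec.query_name
        if truth is not None:
            tr = truth.get(name)
            if tr is None:
                missing.append(name)
                continue
        else:
            tr, _ = parse_truth_name(name)
        if rec.is_unmapped:
            continue
        n_aligned += 1
        strand = "-" if rec.is_reverse else "+"
        pos = rec.reference_start + 1  # pysam is 0-based
        if strand == tr.strand and abs(pos - tr.start) <= tolerance_bp:
            n_correct += 1
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(f"{len(missing)} read ids missing from truth: {shown}")
    return EvalReport(n_reads, n_aligned, n_correct, tolerance_bp)


def repeat_density(genome: Genome, k: int) -> float:
    """D(S|k): fraction of k-mer windows whose k-mer occurs >= 2 times.

    Windows containing N are excluded from numerator and denominator.
    Forward strand only; reverse-complement k-mers are not folded.
    """
    seq = genome.sequence
    n = len(seq)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    counts: dict[str, int] = {}
    valid = 0
    n_positions = [i for i, c in enumerate(seq) if c == "N"]
    n_iter = iter(n_positions + [n + k])
    next_n = next(n_iter)
    for i in range(n - k + 1):
        while next_n < i:
            next_n = next(n_iter)
        if next_n < i + k:
            continue
        valid += 1
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    if valid == 0:
        raise ValueError("no N-free windows at this k")
    repeated = sum(c for c in counts.values() if c >= 2)
    return repeated / valid


def density_profile(genome: Genome, ks: Sequence[int]) -> list[tuple[int, float]]:
    return [(k, repeat_density(genome, k)) for k in ks]


def density_correlation(
    densities: Sequence[float], performance: Sequence[float]
) -> Optional[float]:
    """Pearson r between repeat densities and a performance metric across
    genomes; None when either vector has zero variance."""
    x = np.asarray(densities, dtype=float)
    y = np.asarray(performance, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    return float(stats.pearsonr(x, y).statistic)
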