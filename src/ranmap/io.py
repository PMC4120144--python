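"""Sequence and alignment I/O: FASTA, FASTQ, truth-encoded read names, SAM.

Internal coordinates are 0-based half-open everywhere; SAM records and
truth-encoded read names are 1-based inclusive. Conversion happens only
here, at the I/O boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NON_ACGT = re.compile(r"[^ACGT]")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format."""


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence, uppercase over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if set(self.sequence) - _VALID:
            bad = sorted(set(self.sequence) - _VALID)
            raise ValueError(f"genome contains non-ACGTN characters: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    """A single-end read; qualities are an optional phred string."""

    id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length differs from sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TruthRecord:
    """True origin of a simulated read, in 1-based inclusive reference coords."""

    source_name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid truth interval [{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path) -> Genome:
    """Read the first record of a FASTA file as a Genome.

    Sequence is uppercased; any character outside {A,C,G,T} becomes N.
    Multi-record files are not concatenated: records after the first are
    skipped with a warning.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise FormatError(f"{path}: not a FASTA file (no header line)")
    name = lines[0][1:].split()[0] if len(lines[0]) > 1 else ""
    chunks = []
    for ln in lines[1:]:
        if ln.startswith(">"):
            logger.warning(
                "%s: multiple FASTA records; only the first (%s) is used", path, name
            )
            break
        chunks.append(ln)
    seq = _NON_ACGT.sub("N", "".join(chunks).upper())
    if not seq:
        raise FormatError(f"{path}: FASTA record {name!r} has no sequence")
    return Genome(name=name, sequence=seq)


def read_fastq(path) -> Iterator[Read]:
    """Yield reads from a 4-line-per-record FASTQ file, in file order."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FormatError(f"{path}: truncated FASTQ record #{idx}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"{path}: malformed FASTQ record #{idx}")
            yield Read(
                id=header[1:].strip(),
                sequence=seq.strip().upper(),
                qualities=qual.strip() or None,
            )
            idx += 1


def encode_truth_name(truth: TruthRecord, serial: int) -> str:
    """Encode a truth record into a read name: <source>_<start>_<end>_<strand>_<serial>."""
    return f"{truth.source_name}_{truth.start}_{truth.end}_{truth.strand}_{serial}"


def parse_truth_name(name: str) -> tuple[TruthRecord, int]:
    """Inverse of :func:`encode_truth_name`.

    The source name may itself contain underscores; the last four fields are
    start, end, strand, serial.
    """
    parts = name.split("_")
    if len(parts) < 5:
        raise FormatError(f"read name {name!r} does not encode a truth record")
    source = "_".join(parts[:-4])
    start, end, strand, serial = parts[-4:]
    return TruthRecord(source, int(start), int(end), strand), int(serial)


def _sam_header(genome: Genome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": genome.name, "LN": genome.length}],
        }
    )


def write_sam(results: Iterable, genome: Genome, path) -> None:
    """Write alignment results as SAM.

    One primary record per read: aligned reads carry POS/strand/NM, a second
    candidate (when present) is emitted as a secondary (flag 256) record, and
    unaligned reads get flag 4 with a ZS tag saying why (ambiguous vs
    exhausted attempts).
    """
    header = _sam_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for res in results:
            if res.status == "ALIGNED":
                for rank, cand in enumerate(res.candidates[:2]):
                    if not (0 <= cand.genome_start < genome.length):
                        raise ValueError(
                            f"{res.read_id}: position {cand.genome_start} outside genome"
                        )
                    a = pysam.AlignedSegment(header)
                    a.query_name = res.read_id
                    seq = res.read_sequence
                    if cand.strand == "-":
                        seq = reverse_complement(seq)
                    a.query_sequence = seq
                    a.flag = (16 if cand.strand == "-" else 0) | (256 if rank else 0)
                    a.reference_id = 0
                    a.reference_start = cand.genome_start  # pysam is 0-based; SAM text is 1-based
                    a.mapping_quality = 255
                    a.cigarstring = f"{len(seq)}M"
                    a.set_tag("NM", cand.dist, "i")
                    out.write(a)
            else:
                a = pysam.AlignedSegment(header)
                a.query_name = res.read_id
                a.query_sequence = res.read_sequence
                a.flag = 4
                a.mapping_quality = 0
                a.set_tag(
                    "ZS",
                    "ambiguous" if res.status == "AMBIGUOUS" else "exhausted",
                    "Z",
                )
                out.write(a)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities or 'I' * len(r)}\n")
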