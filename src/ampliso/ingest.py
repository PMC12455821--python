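"""Alignment ingestion: CIGAR parsing, per-read accuracy, filtering, downsampling.

Long-read amplicon experiments produce one alignment file per barcode/sample.
Each aligned read is reduced to its reference exon blocks and intron chain;
per-read accuracy is computed from the CIGAR operation counts and the NM tag as

    accuracy = (M/=/X + I + D - NM) / (M/=/X + I + D)

where an aligner that emits plain ``M`` contributes those bases to the
match/mismatch term (M is matches + mismatches by definition). Reads at or
above the maximum error rate are removed, and each sample is downsampled to a
consistent depth before samples are merged for discovery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# ops that consume reference / query, per the SAM specification
_REF_OPS = set("MDN=X")
_QRY_OPS = set("MIS=X")


class MissingNMError(ValueError):
    """Raised when an alignment lacks the NM tag needed for accuracy."""


class UndefinedAccuracyError(ValueError):
    """Raised when the accuracy denominator (aligned + indel bases) is zero."""


@dataclass(frozen=True)
class CigarCounts:
    """Operation-length totals of one alignment's CIGAR string."""

    n_match_ops: int = 0  # M + '=' + X bases (reference- and query-consuming)
    n_eq: int = 0
    n_x: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_skip: int = 0
    n_clip: int = 0
    nm: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_match_ops", "n_eq", "n_x", "n_ins", "n_del", "n_skip", "n_clip"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_eq + self.n_x > self.n_match_ops:
            raise ValueError("n_eq + n_x cannot exceed n_match_ops")


@dataclass
class AlignedRead:
    """One long read's placement on the reference.

    ``blocks`` are 0-based half-open exon intervals, strictly increasing and
    non-overlapping; ``introns`` are exactly the gaps between consecutive
    blocks.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    accuracy: float
    sample_id: str
    counts: CigarCounts | None = None
    flagged: bool = field(default=False, compare=False)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.introns)

    def validate(self) -> None:
        for (s, e) in self.blocks:
            if e <= s:
                raise ValueError(f"empty block [{s},{e}) in read {self.read_id}")
        for (a, b) in zip(self.blocks, self.blocks[1:]):
            if b[0] <= a[1]:
                raise ValueError(f"blocks not strictly increasing in read {self.read_id}")
        expect = [(a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])]
        if self.introns != expect:
            raise ValueError(f"introns inconsistent with blocks in read {self.read_id}")


@dataclass(frozen=True)
class IngestParams:
    """Per-sample ingestion settings.

    downsample_n: reads kept per sample (uniform, seeded).
    error_max: maximum tolerated per-read error rate; a read whose error rate
        is greater than or equal to this value is removed.
    """

    downsample_n: int = 10_000
    error_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downsample_n < 1:
            raise ValueError("downsample_n must be >= 1")
        if not (0.0 < self.error_max <= 1.0):
            raise ValueError("error_max must be in (0, 1]")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Split a CIGAR string into (op, length) pairs, validating every token."""
    out: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR near {cigar[pos:m.start()]!r}")
        out.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR near {cigar[pos:]!r}")
    return out


def cigar_to_blocks(
    pos: int, cigar: str, nm: int | None = None
) -> tuple[list[tuple[int, int]], list[tuple[int, int]], CigarCounts]:
    """Convert a 1-based alignment position and CIGAR into exon blocks.

    M/=/X/D consume reference; N consumes reference and opens a new block;
    I/S/H consume none. Returned intervals are 0-based half-open.
    """
    if pos < 1:
        raise ValueError("pos must be a 1-based coordinate >= 1")
    ops = parse_cigar(cigar)
    if any(op == "P" for op, _ in ops):
        raise ValueError("padding (P) not supported")
    ref = pos - 1
    block_start = ref
    blocks: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    n_match = n_eq = n_x = n_ins = n_del = n_skip = n_clip = 0
    for op, ln in ops:
        if op in "M=X":
            n_match += ln
            if op == "=":
                n_eq += ln
            elif op == "X":
                n_x += ln
            ref += ln
        elif op == "D":
            n_del += ln
            ref += ln
        elif op == "N":
            if ref > block_start:
                blocks.append((block_start, ref))
            introns.append((ref, ref + ln))
            n_skip += ln
            ref += ln
            block_start = ref
        elif op == "I":
            n_ins += ln
        elif op in "SH":
            n_clip += ln
    if ref > block_start:
        blocks.append((block_start, ref))
    counts = CigarCounts(
        n_match_ops=n_match, n_eq=n_eq, n_x=n_x, n_ins=n_ins, n_del=n_del,
        n_skip=n_skip, n_clip=n_clip, nm=nm,
    )
    return blocks, introns, counts


def read_accuracy(counts: CigarCounts) -> float:
    """Per-read accuracy from CIGAR counts and edit distance.

    Defined as (X + '=' + I + D - NM) / (X + '=' + I + D); plain M bases count
    toward the match/mismatch term. N (intron skips) and clipped bases are
    excluded from both numerator and denominator.
    """
    if counts.nm is None:
        raise MissingNMError("NM tag absent; accuracy undefined")
    denom = counts.n_match_ops + counts.n_ins + counts.n_del
    if denom == 0:
        raise UndefinedAccuracyError("no aligned bases; accuracy undefined")
    return (denom - counts.nm) / denom


def filter_by_accuracy(reads: Iterable[AlignedRead], error_max: float = 0.05) -> list[AlignedRead]:
    """Keep reads with error rate strictly below ``error_max``.

    A read at exactly the threshold (e.g. 5% error, accuracy 0.95) is removed.
    Input order is preserved.
    """
    keep = 1.0 - error_max
    return [r for r in reads if r.accuracy > keep]


def downsample(reads: Sequence[AlignedRead], n: int, seed: int) -> list[AlignedRead]:
    """Uniform random subset of size ``n`` (all reads if fewer), seeded.

    Original read order is preserved in the subset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(reads) <= n:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in sorted(idx)]


def load_alignments(
    path: str | Path,
    sample_id: str,
    strand: str = "+",
    chrom: str | None = None,
) -> list[AlignedRead]:
    """Read primary alignments from a SAM/BAM file into AlignedRead records.

    Unmapped, secondary and supplementary records are dropped (one placement
    per molecule). Every kept record must carry an NM tag. ``strand`` is the
    amplicon's annotated strand: PCR products are strand-ambiguous, so the
    read's own orientation flag is ignored.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if chrom is not None and rec.reference_name != chrom:
                continue
            if not rec.has_tag("NM"):
                raise MissingNMError(
                    f"alignment {rec.query_name} in {path} lacks the NM tag"
                )
            blocks, introns, counts = cigar_to_blocks(
                rec.reference_start + 1, rec.cigarstring, nm=int(rec.get_tag("NM"))
            )
            read = AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                strand=strand,
                blocks=blocks,
                introns=introns,
                accuracy=read_accuracy(counts),
                sample_id=sample_id,
                counts=counts,
            )
            read.validate()
            reads.append(read)
    return reads


def ingest_sample(
    path: str | Path,
    sample_id: str,
    params: IngestParams,
    strand: str = "+",
    chrom: str | None = None,
) -> list[AlignedRead]:
    """Load one sample and apply downsampling then the accuracy filter."""
    reads = load_alignments(path, sample_id, strand=strand, chrom=chrom)
    reads = downsample(reads, params.downsample_n, params.seed)
    return filter_by_accuracy(reads, params.error_max)


__all__ = [
    "AlignedRead",
    "CigarCounts",
    "IngestParams",
    "MissingNMError",
    "UndefinedAccuracyError",
    "cigar_to_blocks",
    "downsample",
    "filter_by_accuracy",
    "ingest_sample",
    "load_alignments",
    "parse_cigar",
    "read_accuracy",
]
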