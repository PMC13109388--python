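"""Aligned reads as ordered gap-separated blocks, and library-strand logic.

A read is represented by its maximal gapless aligned segments ("blocks");
the intervals between consecutive blocks are its gaps, i.e. candidate
splice junctions. Blocks are taken from the alignment's match/deletion/skip
CIGAR operations: reference skips (``N``) always open a gap, short
deletions below ``max_deletion_as_gap`` are absorbed into the surrounding
block (they are indels, not junctions), longer deletions open a gap.

For dUTP-type stranded libraries the mate carrying the annotation strand
is configurable: under ``SECOND_MATE`` (fr-firststrand semantics) the
second mate reports its aligned strand and the first mate the opposite;
``FIRST_MATE`` mirrors this; ``UNSTRANDED`` reports on both strands.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import pysam

__all__ = [
    "StrandProtocol",
    "AlignmentRecord",
    "feature_strand",
    "record_from_alignment",
    "iter_sam",
]

DEFAULT_MAX_DELETION_AS_GAP = 20


class StrandProtocol(enum.Enum):
    """Which mate carries the strand of the annotated feature."""

    FIRST_MATE = "first"
    SECOND_MATE = "second"
    UNSTRANDED = "unstranded"

    @classmethod
    def from_string(cls, value: str) -> "StrandProtocol":
        for member in cls:
            if member.value == value:
                return member
        raise ValueError(f"unknown strand protocol {value!r}")


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read: id, mate flag, chromosome, strand and blocks."""

    read_id: str
    mate: Optional[str]  # "first" | "second" | None (unpaired)
    chrom: str
    aligned_strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.aligned_strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: invalid strand {self.aligned_strand!r}")
        if self.mate not in ("first", "second", None):
            raise ValueError(f"read {self.read_id!r}: invalid mate flag {self.mate!r}")
        if not self.blocks:
            raise ValueError(f"read {self.read_id!r}: at least one block required")
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"read {self.read_id!r}: block ({s},{e}) has end <= start")
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 <= e1:
                raise ValueError(f"read {self.read_id!r}: blocks not ascending with gaps >= 1")

    @property
    def block_count(self) -> int:
        return len(self.blocks)

    @property
    def span(self) -> tuple[int, int]:
        """Full genomic footprint, first block start to last block end."""
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]))


def feature_strand(record: AlignmentRecord, protocol: StrandProtocol) -> str:
    """The annotation strand this read reports on: ``+``, ``-`` or ``both``."""
    if protocol is StrandProtocol.UNSTRANDED:
        return "both"
    if record.mate is None:
        raise ValueError(
            f"read {record.read_id!r}: mate flag required under stranded protocol {protocol.value}"
        )
    reporting_mate = "second" if protocol is StrandProtocol.SECOND_MATE else "first"
    if record.mate == reporting_mate:
        return record.aligned_strand
    return "-" if record.aligned_strand == "+" else "+"


def _blocks_from_cigar(
    start: int, cigartuples, max_deletion_as_gap: int
) -> tuple[tuple[int, int], ...]:
    # BAM ops: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7='=' 8=X
    blocks: list[tuple[int, int]] = []
    block_start = cur = start
    for op, length in cigartuples:
        if op in (0, 7, 8):
            cur += length
        elif op == 2:  # deletion: absorb if short, else junction-like gap
            if length < max_deletion_as_gap:
                cur += length
            else:
                if cur > block_start:
                    blocks.append((block_start, cur))
                block_start = cur = cur + length
        elif op == 3:  # reference skip: always a gap
            if cur > block_start:
                blocks.append((block_start, cur))
            block_start = cur = cur + length
        # I/S/H/P consume no reference
    if cur > block_start:
        blocks.append((block_start, cur))
    return tuple(blocks)


def record_from_alignment(
    aln: pysam.AlignedSegment, max_deletion_as_gap: int = DEFAULT_MAX_DELETION_AS_GAP
) -> AlignmentRecord:
    """Convert a pysam alignment into an :class:`AlignmentRecord`."""
    if aln.is_paired:
        mate = "first" if aln.is_read1 else "second"
    else:
        mate = None
    return AlignmentRecord(
        read_id=aln.query_name,
        mate=mate,
        chrom=aln.reference_name,
        aligned_strand="-" if aln.is_reverse else "+",
        blocks=_blocks_from_cigar(aln.reference_start, aln.cigartuples, max_deletion_as_gap),
    )


def iter_sam(
    path: str | Path, max_deletion_as_gap: int = DEFAULT_MAX_DELETION_AS_GAP
) -> Iterator[AlignmentRecord]:
    """Iterate primary mapped alignments of a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped; duplicates
    are kept (no duplicate filtering is applied anywhere in the pipeline).
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            yield record_from_alignment(aln, max_deletion_as_gap)
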