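"""Read classification against introns and intron-retention quantification.

Each read is intersected with every annotated intron it overlaps by at
least ``min_overlap`` bases on its full genomic span and classified, per
(read, intron) pair, as

* ``UNSPLICED``  — single block crossing at least one intron boundary,
* ``INTRONIC``   — single block fully contained in the intron,
* ``SPLICED``    — split read with a gap matching the intron exactly,
* ``ALT_SPLICED``— split read overlapping the intron, gap not matching,
* ``NO_OVERLAP`` — overlap below the minimum (never counted).

The retention statistic for an intron is

    IR = unspliced / (unspliced + 2 * spliced)

where the factor 2 accounts for a spliced junction being observable from
both exonic sides while a boundary-crossing unspliced read reports on one
boundary only. INTRONIC and ALT_SPLICED reads are counted and reported but
do not enter the statistic by default (``include_intronic_in_numerator``
adds the intronic subcategory to the numerator and denominator).
"""

from __future__ import annotations

import enum
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignments import (
    DEFAULT_MAX_DELETION_AS_GAP,
    AlignmentRecord,
    StrandProtocol,
    feature_strand,
    iter_sam,
)
from .annotation import Intron

__all__ = [
    "ReadClass",
    "classify_read",
    "IntronIndex",
    "count_intron_reads",
    "ir_fraction",
    "quantify_ir",
    "write_ir_table",
    "read_ir_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 3

IR_TABLE_COLUMNS = [
    "intron_id",
    "sample_id",
    "n_unspliced",
    "n_intronic",
    "n_spliced",
    "n_alt",
    "informative_reads",
    "ir_fraction",
]


class ReadClass(enum.Enum):
    UNSPLICED = "unspliced"
    INTRONIC = "intronic"
    SPLICED = "spliced"
    ALT_SPLICED = "alt_spliced"
    NO_OVERLAP = "no_overlap"


def classify_read(
    record: AlignmentRecord, intron: Intron, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> ReadClass:
    """Classify one read against one intron (same chromosome assumed).

    Overlap is computed on the read's full span (first block start to last
    block end) so that an exact-junction read "overlaps" the intron it
    skips. A split read is SPLICED if any of its gaps equals the intron at
    both coordinates, with no tolerance.
    """
    span_start, span_end = record.span
    overlap = min(span_end, intron.end) - max(span_start, intron.start)
    if overlap < min_overlap:
        return ReadClass.NO_OVERLAP
    if record.block_count == 1:
        if span_start >= intron.start and span_end <= intron.end:
            return ReadClass.INTRONIC
        return ReadClass.UNSPLICED
    for gap in record.gaps:
        if gap == (intron.start, intron.end):
            return ReadClass.SPLICED
    return ReadClass.ALT_SPLICED


class IntronIndex:
    """Per-chromosome interval index over an intron set."""

    def __init__(self, introns: Sequence[Intron]):
        self.introns = list(introns)
        self._trees: dict[str, IntervalTree] = {}
        for intron in self.introns:
            self._trees.setdefault(intron.chrom, IntervalTree()).addi(
                intron.start, intron.end, intron
            )
        self.chroms = frozenset(self._trees)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Intron]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


_CLASS_SLOT = {
    ReadClass.UNSPLICED: 0,
    ReadClass.INTRONIC: 1,
    ReadClass.SPLICED: 2,
    ReadClass.ALT_SPLICED: 3,
}


def count_intron_reads(
    alignments: Iterable[AlignmentRecord],
    introns: Sequence[Intron] | IntronIndex,
    protocol: StrandProtocol = StrandProtocol.SECOND_MATE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Count reads per class for every intron, for one sample.

    Every read is evaluated against each intron whose strand matches its
    feature strand and whose interval overlaps the read span; one read may
    increment counts for several introns. Reads on chromosomes absent from
    the annotation are tallied in ``result.attrs['n_skipped_chrom']``.

    Returns a DataFrame indexed by ``intron_id`` with columns
    ``n_unspliced, n_intronic, n_spliced, n_alt`` (one row per intron,
    zeros included).
    """
    index = introns if isinstance(introns, IntronIndex) else IntronIndex(introns)
    counts: dict[str, list[int]] = {i.intron_id: [0, 0, 0, 0] for i in index.introns}
    n_skipped = 0
    for record in alignments:
        if record.chrom not in index.chroms:
            n_skipped += 1
            continue
        strand = feature_strand(record, protocol)
        span_start, span_end = record.span
        for intron in index.overlapping(record.chrom, span_start, span_end):
            if strand != "both" and intron.strand != strand:
                continue
            cls = classify_read(record, intron, min_overlap)
            if cls is not ReadClass.NO_OVERLAP:
                counts[intron.intron_id][_CLASS_SLOT[cls]] += 1
    if n_skipped:
        logger.info("count_intron_reads: %d reads on unannotated chromosomes skipped", n_skipped)
    result = pd.DataFrame.from_dict(
        counts, orient="index", columns=["n_unspliced", "n_intronic", "n_spliced", "n_alt"]
    )
    result.index.name = "intron_id"
    result = result.loc[[i.intron_id for i in index.introns]]
    result.attrs["n_skipped_chrom"] = n_skipped
    return result


def ir_fraction(
    n_unspliced: int,
    n_spliced: int,
    n_intronic: int = 0,
    include_intronic: bool = False,
) -> float:
    """The IR statistic unspliced / (unspliced + 2*spliced).

    Returns NaN when the denominator is zero. With ``include_intronic`` the
    intronic subcategory joins the unspliced numerator (and denominator).
    """
    numerator = n_unspliced + (n_intronic if include_intronic else 0)
    denominator = numerator + 2 * n_spliced
    if denominator <= 0:
        return float("nan")
    return numerator / denominator


def quantify_ir(
    samples: Mapping[str, str | Path | Iterable[AlignmentRecord]],
    introns: Sequence[Intron],
    protocol: StrandProtocol = StrandProtocol.SECOND_MATE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    include_intronic_in_numerator: bool = False,
    max_deletion_as_gap: int = DEFAULT_MAX_DELETION_AS_GAP,
) -> pd.DataFrame:
    """Per-intron, per-sample class counts and IR fractions (long format).

    ``samples`` maps sample ids to SAM/BAM paths or iterables of
    :class:`AlignmentRecord`. Output has one row per (intron, sample) and
    is deterministic given inputs: introns in annotation order within each
    sample, samples in mapping order.
    """
    if not samples:
        raise ValueError("quantify_ir: at least one sample required")
    index = IntronIndex(introns)
    frames = []
    for sample_id, source in samples.items():
        if isinstance(source, (str, Path)):
            try:
                alignments = iter_sam(source, max_deletion_as_gap)
                counts = count_intron_reads(alignments, index, protocol, min_overlap)
            except OSError as exc:
                raise OSError(f"sample {sample_id!r}: cannot read alignments: {exc}") from exc
        else:
            counts = count_intron_reads(source, index, protocol, min_overlap)
        frame = counts.reset_index()
        frame.insert(1, "sample_id", sample_id)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table["informative_reads"] = table["n_unspliced"] + table["n_spliced"]
    table["ir_fraction"] = [
        ir_fraction(u, s, i, include_intronic_in_numerator)
        for u, s, i in zip(table["n_unspliced"], table["n_spliced"], table["n_intronic"])
    ]
    return table[IR_TABLE_COLUMNS]


def write_ir_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_ir_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
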