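"""Independently coded rule-table oracles used to cross-check the package.

Everything here is deliberately written with a different decision
structure (explicit case splits, plain loops, statistics.median) from the
library implementations it verifies, and must stay that way.
"""

from __future__ import annotations

import itertools
import statistics
from collections import defaultdict


def interval_overlap(lo: int, hi: int, istart: int, iend: int) -> int:
    """Length of the intersection of [lo,hi) and [istart,iend), by cases."""
    if hi <= istart or lo >= iend:
        return 0
    if lo <= istart and hi >= iend:
        return iend - istart
    if lo >= istart and hi <= iend:
        return hi - lo
    if lo <= istart:
        return hi - istart
    return iend - lo


def oracle_classify(blocks, istart: int, iend: int, min_overlap: int = 3) -> str:
    """Rule-table classification of one read (as blocks) against one intron."""
    lo = blocks[0][0]
    hi = blocks[-1][1]
    if interval_overlap(lo, hi, istart, iend) < min_overlap:
        return "no_overlap"
    if len(blocks) == 1:
        inside = lo >= istart and hi <= iend
        return "intronic" if inside else "unspliced"
    gaps = []
    previous_end = None
    for s, e in blocks:
        if previous_end is not None:
            gaps.append((previous_end, s))
        previous_end = e
    for gs, ge in gaps:
        if gs == istart and ge == iend:
            return "spliced"
    return "alt_spliced"


def enumerate_block_reads(window_start: int, window_end: int, step: int, n_blocks: int):
    """All reads with ``n_blocks`` blocks whose coordinates lie on the grid."""
    points = range(window_start, window_end + 1, step)
    for combo in itertools.combinations(points, 2 * n_blocks):
        yield tuple((combo[2 * i], combo[2 * i + 1]) for i in range(n_blocks))


# mate/protocol -> feature strand, as an explicit lookup table
_FEATURE_STRAND = {}
for _mate in ("first", "second"):
    for _aligned in ("+", "-"):
        _opp = "-" if _aligned == "+" else "+"
        _FEATURE_STRAND[("second", _mate, _aligned)] = _aligned if _mate == "second" else _opp
        _FEATURE_STRAND[("first", _mate, _aligned)] = _aligned if _mate == "first" else _opp


def oracle_feature_strand(protocol: str, mate, aligned: str) -> str:
    if protocol == "unstranded":
        return "both"
    return _FEATURE_STRAND[(protocol, mate, aligned)]


def brute_force_counts(records, introns, protocol: str, min_overlap: int = 3):
    """Double loop over (read, intron) pairs; the counting oracle."""
    counts = {i.intron_id: defaultdict(int) for i in introns}
    for record in records:
        strand = oracle_feature_strand(protocol, record.mate, record.aligned_strand)
        for intron in introns:
            if record.chrom != intron.chrom:
                continue
            if strand != "both" and strand != intron.strand:
                continue
            cls = oracle_classify(record.blocks, intron.start, intron.end, min_overlap)
            if cls != "no_overlap":
                counts[intron.intron_id][cls] += 1
    return counts


def brute_force_coverage(rows, min_median: int, scope: str):
    """Surviving event ids of the median-coverage rule; the filter oracle.

    ``rows`` is an iterable of (event_id, condition, read_count).
    """
    by_event = defaultdict(lambda: defaultdict(list))
    for event_id, condition, count in rows:
        by_event[event_id][condition].append(count)
    kept = set()
    for event_id, conds in by_event.items():
        verdicts = [statistics.median(counts) >= min_median for counts in conds.values()]
        ok = any(verdicts) if scope == "any_condition" else all(verdicts)
        if ok:
            kept.add(event_id)
    return kept


def brute_force_rmats_filter(events, fdr_threshold: float, min_abs_delta: float):
    """Significant event ids from (event_id, fdr, delta) triples."""
    passed = set()
    for event_id, fdr, delta in events:
        if fdr is None or delta is None:
            continue
        if fdr < fdr_threshold and abs(delta) >= min_abs_delta:
            passed.add(event_id)
    return passed


def brute_force_ri_filter(events, max_flank_exon: int):
    """Surviving event ids from (event_id, as_type, flank_lengths|None)."""
    kept = set()
    for event_id, as_type, flanks in events:
        if as_type != "RI":
            kept.add(event_id)
        elif flanks is not None and all(f <= max_flank_exon for f in flanks):
            kept.add(event_id)
    return kept
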